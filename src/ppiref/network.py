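"""Scored PPI network construction and query answering.

The network is an undirected :mod:`networkx` graph whose edges carry
:class:`~ppiref.scoring.ScoredInteraction` records and whose nodes carry
identifier metadata (symbol, MGI, UniProt), degree, mean incident score and
receptor / transcription-factor flags.  Queries mirror a reference-database
web service: partner tables for one protein, subnetwork extraction around an
input set (0 or 1 neighbor layers, minimum-connection and
confidence/type/tissue/term filters), screen annotation of candidate pair
lists, and export to TSV / PSI-MITAB 2.5 / JSON graph.

Pairs that the user queries explicitly but that are absent from the network
are reported with the sentinel pseudo-score −1; pseudo-rows are requests,
not evidence, so they are exempt from confidence filtering and excluded
from all graph statistics.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .annotation import OntologyDAG, interaction_has_term, interaction_tissues
from .errors import NotFoundError, ParseError, PpirefError
from .mitab import IdMap
from .scoring import CONFIDENCE_PRESETS, ScoredInteraction

#: Sentinel for explicitly queried pairs with no record in the network.
PSEUDO_SCORE = -1.0


@dataclass
class RegulatoryRoles:
    """Receptor and transcription-factor membership from curated input lists."""

    receptors: set[int] = field(default_factory=set)
    transcription_factors: set[int] = field(default_factory=set)

    @classmethod
    def from_tsv(cls, receptors_path=None, tfs_path=None) -> "RegulatoryRoles":
        return cls(
            receptors=_read_id_column(receptors_path) if receptors_path else set(),
            transcription_factors=_read_id_column(tfs_path) if tfs_path else set(),
        )


def _read_id_column(path: str | Path) -> set[int]:
    out: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                out.add(int(line.split("\t")[0]))
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer Entrez ID"
                ) from exc
    return out


class PPINetwork:
    """Scored undirected interaction network with identifier resolution."""

    def __init__(self, graph: nx.Graph, idmap: IdMap | None = None):
        self.graph = graph
        self._symbol: dict[str, list[int]] = {}
        self._mgi: dict[str, int] = {}
        self._uniprot: dict[str, int] = {}
        for node, attrs in graph.nodes(data=True):
            if attrs.get("symbol"):
                self._symbol.setdefault(attrs["symbol"], []).append(node)
            if attrs.get("mgi"):
                self._mgi[attrs["mgi"]] = node
            if attrs.get("uniprot"):
                self._uniprot[attrs["uniprot"]] = node

    @property
    def n_proteins(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_interactions(self) -> int:
        return self.graph.number_of_edges()

    def scores(self) -> list[float]:
        return [d["score"] for _, _, d in self.graph.edges(data=True)]

    def resolve(self, identifier: str | int) -> int:
        """Resolve any accepted identifier (Entrez, symbol, MGI, UniProt).

        Precedence on ambiguity: all-digit strings are Entrez, then exact
        symbol, then MGI accession, then UniProt accession.  An ambiguous
        symbol raises an error listing the candidates.
        """
        if isinstance(identifier, int):
            if identifier in self.graph:
                return identifier
            raise NotFoundError(f"Entrez ID {identifier} not in network")
        ident = identifier.strip()
        if re.fullmatch(r"\d+", ident):
            entrez = int(ident)
            if entrez in self.graph:
                return entrez
            raise NotFoundError(f"Entrez ID {entrez} not in network")
        hits = self._symbol.get(ident, [])
        if len(hits) == 1:
            return hits[0]
        if len(hits) > 1:
            raise NotFoundError(
                f"symbol {ident!r} is ambiguous: candidates {sorted(hits)}"
            )
        if ident in self._mgi:
            return self._mgi[ident]
        if ident in self._uniprot:
            return self._uniprot[ident]
        raise NotFoundError(f"identifier {ident!r} not found in network")


def build_network(
    scored: Iterable[ScoredInteraction],
    idmap: IdMap | None = None,
    roles: RegulatoryRoles | None = None,
) -> PPINetwork:
    """Assemble the scored network.

    Nodes are the union of pair members (so no isolated nodes can arise;
    homodimer evidence yields a retained self-loop node).  Each node gets
    its identifiers, degree (self-loops count once), mean incident score and
    receptor/TF flags.
    """
    g = nx.Graph()
    for si in scored:
        a, b = si.pair
        g.add_edge(a, b, score=si.score, record=si)
    for node in g.nodes:
        incident = [g.edges[e]["score"] for e in g.edges(node)]
        g.nodes[node]["degree"] = len(list(g.neighbors(node)))  # self-loop once
        g.nodes[node]["mean_score"] = (
            sum(incident) / len(incident) if incident else 0.0
        )
        rec = idmap.by_entrez(node) if idmap is not None else None
        g.nodes[node]["symbol"] = rec.symbol if rec else ""
        g.nodes[node]["mgi"] = rec.mgi if rec else ""
        g.nodes[node]["uniprot"] = rec.uniprot if rec else ""
        g.nodes[node]["receptor"] = bool(roles and node in roles.receptors)
        g.nodes[node]["tf"] = bool(
            roles and node in roles.transcription_factors
        )
    return PPINetwork(g, idmap)


@dataclass
class QueryOptions:
    """Subnetwork-query knobs mirroring the REST/web contract.

    ``layers`` 0 restricts to edges within the input set, 1 adds first-level
    neighbors; ``min_connections`` drops neighbors linked to fewer input
    proteins; ``threshold`` is a numeric cutoff in [0, 1] or a named preset
    ("medium"/"high"); type/tissue/term filters are conjunctive.
    """

    layers: int = 1
    min_connections: int = 1
    threshold: float | str = 0.0
    type_filter: set[str] | None = None
    tissue_filter: str | None = None
    term_filters: Sequence[str] | None = None
    include_neighbor_edges: bool = True

    def numeric_threshold(self) -> float:
        if isinstance(self.threshold, str):
            try:
                return CONFIDENCE_PRESETS[self.threshold.lower()]
            except KeyError:
                raise PpirefError(
                    f"unknown confidence level {self.threshold!r}; "
                    f"use one of {sorted(CONFIDENCE_PRESETS)}"
                ) from None
        return float(self.threshold)

    def validate(self) -> None:
        if self.layers not in (0, 1):
            raise PpirefError(f"layers must be 0 or 1, got {self.layers}")
        thr = self.numeric_threshold()
        if not (0.0 <= thr <= 1.0):
            raise PpirefError(f"threshold must lie in [0, 1], got {thr}")
        if self.min_connections < 1:
            raise PpirefError("min_connections must be a positive integer")


@dataclass
class QueryResult:
    """A queried subnetwork plus the pseudo-score rows for absent pairs."""

    graph: nx.Graph
    pseudo_pairs: list[tuple[int | str, int | str]] = field(default_factory=list)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"entrez_a": min(a, b), "entrez_b": max(a, b), "score": d["score"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        rows += [
            {"entrez_a": a, "entrez_b": b, "score": PSEUDO_SCORE}
            for a, b in self.pseudo_pairs
        ]
        return pd.DataFrame(rows, columns=["entrez_a", "entrez_b", "score"])


def protein_query(net: PPINetwork, identifier: str | int) -> pd.DataFrame:
    """Partner table of one protein, sorted by descending confidence.

    Each row carries the partner's identifiers, the interaction score and
    the evidence origin (publications, techniques, interolog species).
    An unresolvable identifier raises :class:`NotFoundError`; a resolvable
    protein with no partners yields an empty table.
    """
    node = net.resolve(identifier)
    rows = []
    for partner in net.graph.neighbors(node):
        d = net.graph.edges[node, partner]
        rec: ScoredInteraction = d["record"]
        attrs = net.graph.nodes[partner]
        rows.append(
            {
                "partner_entrez": partner,
                "partner_symbol": attrs.get("symbol", ""),
                "partner_mgi": attrs.get("mgi", ""),
                "partner_uniprot": attrs.get("uniprot", ""),
                "score": d["score"],
                "publications": "|".join(sorted(rec.evidence.studies)),
                "techniques": "|".join(sorted(rec.evidence.techniques)),
                "interolog_species": "|".join(
                    sorted(rec.evidence.interolog_species)
                ),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "partner_entrez",
            "partner_symbol",
            "partner_mgi",
            "partner_uniprot",
            "score",
            "publications",
            "techniques",
            "interolog_species",
        ],
    )
    if len(table):
        table = table.sort_values(
            ["score", "partner_entrez"], ascending=[False, True]
        ).reset_index(drop=True)
    return table


def _edge_passes(
    record: ScoredInteraction,
    pair: tuple[int, int],
    opts: QueryOptions,
    annotations: Mapping[int, set[str]] | None,
    dag: OntologyDAG | None,
    calls: pd.DataFrame | None,
) -> bool:
    if record.score < opts.numeric_threshold():
        return False
    if opts.type_filter is not None:
        if not (record.evidence.interaction_types & set(opts.type_filter)):
            return False
    if opts.tissue_filter is not None:
        if calls is None:
            raise PpirefError("tissue filter requires presence calls")
        if opts.tissue_filter not in interaction_tissues(pair, calls):
            return False
    if opts.term_filters:
        if annotations is None or dag is None:
            raise PpirefError("term filter requires annotations and an ontology")
        for term in opts.term_filters:
            if not interaction_has_term(pair, annotations, dag, term):
                return False
    return True


def network_query(
    net: PPINetwork,
    inputs: Sequence[str | int | tuple],
    opts: QueryOptions | None = None,
    annotations: Mapping[int, set[str]] | None = None,
    dag: OntologyDAG | None = None,
    calls: pd.DataFrame | None = None,
) -> QueryResult:
    """Extract a filtered subnetwork around an input set.

    ``inputs`` mixes single proteins and explicit pairs (2-tuples).  With
    ``layers=1`` the subnetwork covers the input proteins, their surviving
    first-level neighbors, every edge touching the input set and (by
    default) edges among the selected neighbors; with ``layers=0`` only
    edges within the input set are returned.  Neighbors must interact with
    at least ``min_connections`` input proteins to survive.  Explicitly
    queried pairs absent from the network are reported with pseudo-score −1.
    """
    if opts is None:
        opts = QueryOptions()
    opts.validate()
    if not inputs:
        raise PpirefError("network query requires a nonempty input set")

    input_nodes: set[int] = set()
    pseudo: list[tuple] = []
    for item in inputs:
        if isinstance(item, tuple):
            a_raw, b_raw = item
            try:
                a = net.resolve(a_raw)
            except NotFoundError:
                a = None
            try:
                b = net.resolve(b_raw)
            except NotFoundError:
                b = None
            input_nodes.update(n for n in (a, b) if n is not None)
            if a is None or b is None or not net.graph.has_edge(a, b):
                pseudo.append((a if a is not None else a_raw,
                               b if b is not None else b_raw))
        else:
            input_nodes.add(net.resolve(item))

    g = net.graph
    if opts.layers == 0:
        selected = set(input_nodes)
    else:
        neighbors: set[int] = set()
        for n in input_nodes:
            neighbors.update(g.neighbors(n))
        neighbors -= input_nodes
        kept = {
            nb
            for nb in neighbors
            if sum(1 for x in g.neighbors(nb) if x in input_nodes)
            >= opts.min_connections
        }
        selected = input_nodes | kept

    sub = nx.Graph()
    sub.add_nodes_from((n, dict(g.nodes[n])) for n in selected if n in g)
    for a, b, d in g.edges(data=True):
        if a not in selected or b not in selected:
            continue
        touches_input = a in input_nodes or b in input_nodes
        if not touches_input and not (
            opts.layers == 1 and opts.include_neighbor_edges
        ):
            continue
        pair = (min(a, b), max(a, b))
        if _edge_passes(d["record"], pair, opts, annotations, dag, calls):
            sub.add_edge(a, b, **d)
    return QueryResult(graph=sub, pseudo_pairs=pseudo)


def filter_confidence(
    target: QueryResult | nx.Graph, threshold: float
) -> QueryResult | nx.Graph:
    """Keep edges with score >= threshold (inclusive).

    Pseudo-score rows are exempt: they mark user-requested absences, not
    evidence.  Returns the same shape as the input.
    """
    if not (0.0 <= threshold <= 1.0):
        raise PpirefError(f"threshold must lie in [0, 1], got {threshold}")
    if isinstance(target, QueryResult):
        return QueryResult(
            graph=filter_confidence(target.graph, threshold),
            pseudo_pairs=list(target.pseudo_pairs),
        )
    out = nx.Graph()
    out.add_nodes_from(target.nodes(data=True))
    out.add_edges_from(
        (a, b, d) for a, b, d in target.edges(data=True) if d["score"] >= threshold
    )
    return out


def parse_screen_file(path: str | Path) -> list[tuple[str, str]]:
    """Read candidate pairs from a tab-, comma- or semicolon-separated file."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[\t,;]", line)
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected two identifiers, "
                    f"got {line!r}"
                )
            pairs.append((parts[0], parts[1]))
    return pairs


def screen_annotate(
    pairs: Sequence[tuple[str | int, str | int]], net: PPINetwork
) -> pd.DataFrame:
    """Annotate a candidate pair list with reference scores.

    Adds exactly one ``score`` column: pairs present in the network get
    their confidence score, absent (or unresolvable) pairs get −1.  Row
    order is preserved.
    """
    rows = []
    for a_raw, b_raw in pairs:
        score = PSEUDO_SCORE
        try:
            a, b = net.resolve(a_raw), net.resolve(b_raw)
        except NotFoundError:
            pass
        else:
            if net.graph.has_edge(a, b):
                score = net.graph.edges[a, b]["score"]
        rows.append({"a": a_raw, "b": b_raw, "score": score})
    return pd.DataFrame(rows, columns=["a", "b", "score"])


def _mitab_line(a: int, b: int, d: Mapping, graph: nx.Graph) -> str:
    rec: ScoredInteraction = d["record"]
    ev = rec.evidence

    def _id(node: int) -> str:
        return f"entrez gene/locuslink:{node}"

    def _alt(node: int) -> str:
        sym = graph.nodes[node].get("symbol", "")
        return f"entrez gene/locuslink:{sym}" if sym else "-"

    def _mi_terms(codes: Iterable[str]) -> str:
        codes = sorted(codes)
        if not codes:
            return "-"
        return "|".join(f'psi-mi:"{c}"(unspecified)' for c in codes)

    cols = [
        _id(a),
        _id(b),
        _alt(a),
        _alt(b),
        "-",
        "-",
        _mi_terms(ev.techniques),
        "-",
        "|".join(sorted(ev.studies)) or "-",
        "taxid:10090(mouse)",
        "taxid:10090(mouse)",
        _mi_terms(ev.interaction_types),
        "-",
        "-",
        f"score:{rec.score:.6f}",
    ]
    return "\t".join(cols)


def export(
    result: QueryResult,
    fmt: str,
    path: str | Path,
) -> Path:
    """Write a query result as ``tsv``, ``mitab`` or ``json-graph``.

    The MITAB output is valid PSI-MITAB 2.5 and round-trips through
    :func:`ppiref.mitab.parse_mitab` to the same pair set; the JSON graph
    (node-link form, with node and edge attributes) stands in for a browser
    visualization.
    """
    path = Path(path)
    if fmt == "tsv":
        result.edge_table().to_csv(path, sep="\t", index=False)
    elif fmt == "mitab":
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(f"col{i}" for i in range(1, 16)) + "\n")
            for a, b, d in result.graph.edges(data=True):
                fh.write(_mitab_line(a, b, d, result.graph) + "\n")
    elif fmt == "json-graph":
        data = nx.node_link_data(
            _strip_records(result.graph), edges="edges"
        )
        data["pseudo_pairs"] = [
            {"a": a, "b": b, "score": PSEUDO_SCORE}
            for a, b in result.pseudo_pairs
        ]
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)
    else:
        raise PpirefError(
            f"unknown export format {fmt!r}; use tsv, mitab or json-graph"
        )
    return path


def _strip_records(graph: nx.Graph) -> nx.Graph:
    """Copy a graph with JSON-serializable attributes only."""
    out = nx.Graph()
    out.add_nodes_from(graph.nodes(data=True))
    for a, b, d in graph.edges(data=True):
        attrs = {k: v for k, v in d.items() if k != "record"}
        rec: ScoredInteraction | None = d.get("record")
        if rec is not None:
            attrs["studies"] = sorted(rec.evidence.studies)
            attrs["techniques"] = sorted(rec.evidence.techniques)
            attrs["interolog_species"] = sorted(rec.evidence.interolog_species)
        out.add_edge(a, b, **attrs)
    return out
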