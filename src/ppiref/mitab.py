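"""PSI-MITAB 2.5 ingest: parsing, interaction-type filtering, identifier
mapping and aggregation of raw records into per-pair evidence bundles.

The pipeline mirrors how curated interaction snapshots are assembled from
federated molecular-interaction providers: every provider row is parsed into
a :class:`RawInteractionRow`, rows are restricted to association-like
interaction types, provider identifiers are translated to canonical Entrez
IDs through an :class:`IdMap` (rows failing to map are discarded and
tallied), and the survivors are collapsed into one :class:`EvidenceBundle`
per unordered protein pair.  The bundle's study / technique / interolog sets
are the ``n`` inputs of the confidence score.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ParseError

MISSING = "-"

#: Interaction-type whitelist: association, physical association, direct
#: interaction and colocalization.
DEFAULT_ALLOWED_TYPES = frozenset({"MI:0914", "MI:0915", "MI:0407", "MI:0403"})

#: NCBI taxon of Mus musculus; never counted as interolog support.
MOUSE_TAXON = "10090"

_MI_RE = re.compile(r"MI:\d{4}")
MITAB_COLUMNS = 15


@dataclass(frozen=True)
class RawInteractionRow:
    """One data line of a PSI-MITAB 2.5 file, reduced to the fields the
    pipeline consumes."""

    interactor_a_raw: str
    interactor_b_raw: str
    detection_method: str
    publication: str
    taxid_a: str
    taxid_b: str
    interaction_type: str
    source_db: str


@dataclass(frozen=True)
class CanonicalRow:
    """A raw row whose interactors have been mapped to Entrez IDs."""

    entrez_a: int
    entrez_b: int
    detection_method: str
    publication: str
    interaction_type: str
    source_db: str


@dataclass(frozen=True)
class IdRecord:
    entrez: int
    symbol: str
    mgi: str
    uniprot: str


class IdMap:
    """Provider-identifier -> canonical record lookup.

    Lookup of an unmapped identifier reports absence (``get`` returns
    ``None``); a record is never fabricated.
    """

    def __init__(self, entries: Mapping[str, IdRecord]):
        for provider_id, rec in entries.items():
            if rec.entrez <= 0:
                raise ValueError(
                    f"identifier map entry {provider_id!r} has non-positive "
                    f"Entrez ID {rec.entrez}"
                )
        self._entries = dict(entries)
        self._by_entrez = {rec.entrez: rec for rec in self._entries.values()}

    def get(self, provider_id: str) -> IdRecord | None:
        return self._entries.get(provider_id)

    def by_entrez(self, entrez: int) -> IdRecord | None:
        return self._by_entrez.get(entrez)

    def __len__(self) -> int:
        return len(self._entries)

    def records(self) -> Iterable[IdRecord]:
        return self._by_entrez.values()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IdMap":
        """Read a 5-column TSV (provider_id, entrez, symbol, mgi, uniprot)."""
        entries: dict[str, IdRecord] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 5:
                    raise ParseError(
                        f"{path}: line {lineno}: expected 5 columns, got {len(parts)}"
                    )
                provider_id, entrez, symbol, mgi, uniprot = parts[:5]
                try:
                    entrez_i = int(entrez)
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: line {lineno}: non-integer Entrez ID {entrez!r}"
                    ) from exc
                entries[provider_id] = IdRecord(entrez_i, symbol, mgi, uniprot)
        return cls(entries)


@dataclass
class EvidenceBundle:
    """All evidence for one unordered protein pair.

    ``studies`` feeds the study sub-score, ``techniques`` (via the
    reliability table) the technique sub-score and ``interolog_species`` the
    cross-species sub-score.
    """

    pair: tuple[int, int]
    interaction_types: set[str] = field(default_factory=set)
    studies: set[str] = field(default_factory=set)
    techniques: set[str] = field(default_factory=set)
    interolog_species: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        a, b = self.pair
        self.pair = (a, b) if a <= b else (b, a)


@dataclass
class DiscardReport:
    """Tally of rows dropped because one or both interactors failed to map."""

    kept: int = 0
    unmapped_a: int = 0
    unmapped_b: int = 0
    unmapped_both: int = 0

    @property
    def discarded(self) -> int:
        return self.unmapped_a + self.unmapped_b + self.unmapped_both

    @property
    def total(self) -> int:
        return self.kept + self.discarded


def _first_token(cell: str) -> str:
    """First database:accession token of a pipe-separated MITAB cell."""
    return cell.split("|")[0].strip()


def _mi_code(cell: str) -> str:
    """Extract the MI code from ``psi-mi:"MI:0915"(physical association)``."""
    if cell.strip() in ("", MISSING):
        return MISSING
    m = _MI_RE.search(cell)
    return m.group(0) if m else MISSING


def _taxid(cell: str) -> str:
    tok = _first_token(cell).split("(")[0]
    if tok.startswith("taxid:"):
        tok = tok[len("taxid:"):]
    return tok


def _publication(cell: str) -> str:
    tok = _first_token(cell)
    return tok if tok else MISSING


def parse_mitab(path: str | Path) -> list[RawInteractionRow]:
    """Parse a PSI-MITAB 2.5 file into raw interaction rows.

    Lines starting with ``#`` are treated as headers/comments.  Data lines
    need at least 15 tab-separated columns; extra columns (MITAB 2.6+) are
    ignored.  A shorter data line raises :class:`ParseError` naming the line
    number.
    """
    rows: list[RawInteractionRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < MITAB_COLUMNS:
                raise ParseError(
                    f"{path}: line {lineno}: MITAB 2.5 requires "
                    f"{MITAB_COLUMNS} columns, got {len(parts)}"
                )
            rows.append(
                RawInteractionRow(
                    interactor_a_raw=_first_token(parts[0]),
                    interactor_b_raw=_first_token(parts[1]),
                    detection_method=_mi_code(parts[6]),
                    publication=_publication(parts[8]),
                    taxid_a=_taxid(parts[9]),
                    taxid_b=_taxid(parts[10]),
                    interaction_type=_mi_code(parts[11]),
                    source_db=_first_token(parts[12]),
                )
            )
    return rows


def filter_interaction_types(
    rows: Sequence[RawInteractionRow],
    allowed: Iterable[str] = DEFAULT_ALLOWED_TYPES,
    mi_dag=None,
) -> list[RawInteractionRow]:
    """Keep rows whose interaction type is in ``allowed``.

    When an MI-ontology DAG (anything with a ``descendants(term)`` method,
    e.g. :class:`ppiref.annotation.OntologyDAG`) is supplied, descendants of
    allowed codes are accepted too.  Row order is preserved.
    """
    accepted = set(allowed)
    if mi_dag is not None:
        for code in list(accepted):
            if code in mi_dag.terms:
                accepted |= mi_dag.descendants(code)
    return [r for r in rows if r.interaction_type in accepted]


def map_and_discard(
    rows: Sequence[RawInteractionRow], idmap: IdMap
) -> tuple[list[CanonicalRow], DiscardReport]:
    """Map interactors to Entrez IDs, discarding rows with unmapped proteins.

    Returns the canonicalized rows plus a tally of discards by cause
    (unmapped A, unmapped B, both).  Kept + discarded always equals the
    input row count.
    """
    kept: list[CanonicalRow] = []
    report = DiscardReport()
    for row in rows:
        rec_a = idmap.get(row.interactor_a_raw)
        rec_b = idmap.get(row.interactor_b_raw)
        if rec_a is None and rec_b is None:
            report.unmapped_both += 1
        elif rec_a is None:
            report.unmapped_a += 1
        elif rec_b is None:
            report.unmapped_b += 1
        else:
            report.kept += 1
            kept.append(
                CanonicalRow(
                    entrez_a=rec_a.entrez,
                    entrez_b=rec_b.entrez,
                    detection_method=row.detection_method,
                    publication=row.publication,
                    interaction_type=row.interaction_type,
                    source_db=row.source_db,
                )
            )
    return kept, report


def aggregate(rows: Sequence[CanonicalRow]) -> dict[tuple[int, int], EvidenceBundle]:
    """Collapse canonicalized rows into one evidence bundle per unordered pair.

    Studies and techniques are unions over all rows of a pair, so exact
    duplicates (same pair, study and method) have no effect; distinct studies
    or methods accumulate as evidence.  Missing (``-``) publication or method
    fields contribute nothing.  Self-interactions are retained as single-node
    bundles.  Proteins enter the result only through bundles, so isolated
    proteins cannot exist by construction.
    """
    bundles: dict[tuple[int, int], EvidenceBundle] = {}
    for row in rows:
        pair = (min(row.entrez_a, row.entrez_b), max(row.entrez_a, row.entrez_b))
        bundle = bundles.get(pair)
        if bundle is None:
            bundle = bundles[pair] = EvidenceBundle(pair=pair)
        if row.interaction_type != MISSING:
            bundle.interaction_types.add(row.interaction_type)
        if row.publication != MISSING:
            bundle.studies.add(row.publication)
        if row.detection_method != MISSING:
            bundle.techniques.add(row.detection_method)
    return bundles


def attach_interologs(
    bundles: Mapping[tuple[int, int], EvidenceBundle],
    interolog_table: Mapping[tuple[int, int], Iterable[str]],
) -> dict[tuple[int, int], EvidenceBundle]:
    """Attach cross-species (interolog) support to each bundle.

    A bundle's ``interolog_species`` becomes the table entry for its pair
    (empty when absent).  The mouse taxon is excluded defensively; other
    fields are untouched.
    """
    normalized = {
        (min(a, b), max(a, b)): {str(t) for t in taxa} - {MOUSE_TAXON}
        for (a, b), taxa in interolog_table.items()
    }
    out: dict[tuple[int, int], EvidenceBundle] = {}
    for pair, bundle in bundles.items():
        out[pair] = replace(
            bundle,
            interaction_types=set(bundle.interaction_types),
            studies=set(bundle.studies),
            techniques=set(bundle.techniques),
            interolog_species=set(normalized.get(pair, set())),
        )
    return out


def load_interolog_table(path: str | Path) -> dict[tuple[int, int], set[str]]:
    """Read a TSV of (entrez_a, entrez_b, comma-separated taxon IDs)."""
    table: dict[tuple[int, int], set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(parts)}"
                )
            try:
                a, b = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer Entrez ID"
                ) from exc
            taxa = {t.strip() for t in parts[2].split(",") if t.strip()}
            key = (min(a, b), max(a, b))
            table.setdefault(key, set()).update(taxa)
    return table


def ingest(
    mitab_path: str | Path,
    idmap: IdMap,
    interolog_table: Mapping[tuple[int, int], Iterable[str]] | None = None,
    allowed_types: Iterable[str] = DEFAULT_ALLOWED_TYPES,
) -> tuple[dict[tuple[int, int], EvidenceBundle], DiscardReport]:
    """Full ingest convenience: parse -> filter -> map -> aggregate -> interologs."""
    rows = parse_mitab(mitab_path)
    rows = filter_interaction_types(rows, allowed_types)
    canonical, report = map_and_discard(rows, idmap)
    bundles = aggregate(canonical)
    if interolog_table is not None:
        bundles = attach_interologs(bundles, interolog_table)
    return bundles, report
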