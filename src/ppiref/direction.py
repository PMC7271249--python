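"""Shortest-path directionality inference and effect overlay.

Signal tends to flow from the cell surface to the nucleus, so orientations
are inferred from shortest paths between source proteins (receptors by
default) and sink proteins (transcription factors by default): every edge
traversed by at least one minimum-hop path between a source and a sink is
oriented in the direction of traversal.  An edge traversed in both
directions across any of the enumerated paths is left undirected — the
conflict rule.  The weighted variant keeps, per (source, sink) pair, only
the minimum-hop path with the highest cumulative confidence score.

Curated direction/effect annotations (activation or inhibition of the
target by the source) can be overlaid afterwards and override inference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import log
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import EndpointError, ParseError, PpirefError
from .network import PPINetwork, RegulatoryRoles

ACTIVATION = "activation"
INHIBITION = "inhibition"


@dataclass(frozen=True)
class EdgeDirection:
    """Direction state of one undirected edge.

    ``orientation`` is an ordered (source, target) tuple or ``None`` when
    the edge is undirected; ``conflicted`` marks edges traversed in both
    directions; ``on_path`` marks edges used by at least one retained path.
    """

    orientation: tuple[int, int] | None = None
    on_path: bool = False
    conflicted: bool = False
    effects: tuple[str, ...] = ()


class DirectionOverlay:
    """Per-edge orientation/effect assignment over a subnetwork's edges."""

    def __init__(self, edges: Iterable[tuple[int, int]]):
        self._state: dict[tuple[int, int], EdgeDirection] = {
            _key(a, b): EdgeDirection() for a, b in edges
        }

    @staticmethod
    def for_graph(graph: nx.Graph) -> "DirectionOverlay":
        return DirectionOverlay(graph.edges())

    def __contains__(self, edge: tuple[int, int]) -> bool:
        return _key(*edge) in self._state

    def __getitem__(self, edge: tuple[int, int]) -> EdgeDirection:
        return self._state[_key(*edge)]

    def edges(self) -> dict[tuple[int, int], EdgeDirection]:
        return dict(self._state)

    def set(self, edge: tuple[int, int], state: EdgeDirection) -> None:
        key = _key(*edge)
        if key not in self._state:
            raise PpirefError(
                f"cannot assign direction to edge {edge} absent from subnetwork"
            )
        self._state[key] = state

    def oriented_edges(self) -> list[tuple[int, int]]:
        """Ordered (source, target) tuples of every directed edge."""
        return [
            st.orientation
            for st in self._state.values()
            if st.orientation is not None
        ]

    def as_digraph(self) -> nx.DiGraph:
        """Directed view containing only the oriented edges."""
        dg = nx.DiGraph()
        dg.add_edges_from(self.oriented_edges())
        return dg


def _key(a, b) -> tuple:
    return (a, b) if a <= b else (b, a)


def _check_endpoints(
    graph: nx.Graph, sources: Iterable[int], sinks: Iterable[int]
) -> tuple[set[int], set[int]]:
    sources, sinks = set(sources), set(sinks)
    if not sources or not sinks:
        raise EndpointError("sources and sinks must be nonempty")
    missing = (sources | sinks) - set(graph.nodes)
    if missing:
        raise EndpointError(
            f"endpoint proteins {sorted(missing)} are not in the subnetwork"
        )
    return sources, sinks


def _assign(traversals: Mapping[tuple, set[tuple]], overlay: DirectionOverlay) -> None:
    for key, dirs in traversals.items():
        if len(dirs) == 1:
            overlay.set(key, EdgeDirection(orientation=next(iter(dirs)), on_path=True))
        else:  # traversed both ways by different paths -> no direction
            overlay.set(
                key, EdgeDirection(orientation=None, on_path=True, conflicted=True)
            )


def _record_path(path: list[int], traversals: dict) -> None:
    for u, v in zip(path, path[1:]):
        traversals.setdefault(_key(u, v), set()).add((u, v))


def infer_unweighted(
    subnet: PPINetwork | nx.Graph,
    sources: Iterable[int],
    sinks: Iterable[int],
) -> DirectionOverlay:
    """Orient edges used by *all* minimum-hop source-to-sink paths.

    For every (source, sink) pair, every shortest path (by hop count) is
    enumerated; each traversed edge is oriented source-to-sink-ward.  Edges
    traversed in conflicting directions stay undirected; untraversed edges
    stay undirected with ``on_path`` false.  Disconnected pairs contribute
    nothing.
    """
    graph = subnet.graph if isinstance(subnet, PPINetwork) else subnet
    sources, sinks = _check_endpoints(graph, sources, sinks)
    overlay = DirectionOverlay.for_graph(graph)
    traversals: dict[tuple, set[tuple]] = {}
    for s in sorted(sources):
        for t in sorted(sinks):
            if s == t or not nx.has_path(graph, s, t):
                continue
            for path in nx.all_shortest_paths(graph, s, t):
                _record_path(path, traversals)
    _assign(traversals, overlay)
    return overlay


def infer_weighted(
    subnet: PPINetwork | nx.Graph,
    sources: Iterable[int],
    sinks: Iterable[int],
    method: str = "min_hop",
) -> DirectionOverlay:
    """Orient edges of the best-confidence shortest path per endpoint pair.

    With the default ``min_hop`` method, the candidates for each (source,
    sink) pair are the minimum-hop paths, and only the one maximizing the
    sum of edge confidence scores is retained (ties broken by
    lexicographically smallest node sequence, for determinism).  With
    ``method="neglog"`` a Dijkstra search on edge weight −log(score) is used
    instead and all minimum-weight paths are retained.
    """
    graph = subnet.graph if isinstance(subnet, PPINetwork) else subnet
    sources, sinks = _check_endpoints(graph, sources, sinks)
    overlay = DirectionOverlay.for_graph(graph)
    traversals: dict[tuple, set[tuple]] = {}

    if method == "neglog":
        eps = 1e-12
        for a, b, d in graph.edges(data=True):
            graph.edges[a, b]["_neglog"] = -log(max(d.get("score", eps), eps))
        for s in sorted(sources):
            for t in sorted(sinks):
                if s == t or not nx.has_path(graph, s, t):
                    continue
                for path in nx.all_shortest_paths(graph, s, t, weight="_neglog"):
                    _record_path(path, traversals)
    elif method == "min_hop":
        def _path_score(p: list[int]) -> float:
            return sum(
                graph.edges[u, v].get("score", 0.0) for u, v in zip(p, p[1:])
            )

        for s in sorted(sources):
            for t in sorted(sinks):
                if s == t or not nx.has_path(graph, s, t):
                    continue
                candidates = list(nx.all_shortest_paths(graph, s, t))
                best_score = max(_path_score(p) for p in candidates)
                # deterministic tie-break: lexicographically smallest sequence
                best = min(
                    p for p in candidates if _path_score(p) == best_score
                )
                _record_path(best, traversals)
    else:
        raise PpirefError(f"unknown weighting method {method!r}")
    _assign(traversals, overlay)
    return overlay


def default_endpoints(
    subnet: PPINetwork | nx.Graph, roles: RegulatoryRoles
) -> tuple[set[int], set[int]]:
    """Receptors present in the subnetwork as sources, TFs as sinks."""
    graph = subnet.graph if isinstance(subnet, PPINetwork) else subnet
    nodes = set(graph.nodes)
    sources = roles.receptors & nodes
    sinks = roles.transcription_factors & nodes
    if not sources:
        raise EndpointError(
            "no receptor is present in the subnetwork; "
            "supply user-defined sources"
        )
    if not sinks:
        raise EndpointError(
            "no transcription factor is present in the subnetwork; "
            "supply user-defined sinks"
        )
    return sources, sinks


def overlay_effects(
    overlay: DirectionOverlay,
    effects: Mapping[tuple[int, int], str],
) -> DirectionOverlay:
    """Overlay curated direction/effect entries, overriding inference.

    An entry (source, target) -> effect fixes the edge's orientation and
    effect label.  Entries present in both orientations mark the edge
    undirected with both effects attached.  Entries for edges absent from
    the subnetwork are ignored.
    """
    out = DirectionOverlay([])
    out._state = overlay.edges()
    by_edge: dict[tuple, list[tuple[tuple[int, int], str]]] = {}
    for (s, t), effect in effects.items():
        by_edge.setdefault(_key(s, t), []).append(((s, t), effect))
    for key, entries in by_edge.items():
        if key not in out._state:
            continue
        orientations = {o for o, _ in entries}
        current = out._state[key]
        if len(orientations) > 1:
            out._state[key] = replace(
                current,
                orientation=None,
                conflicted=True,
                effects=tuple(e for _, e in sorted(entries)),
            )
        else:
            (orientation, effect), = entries[:1] or [(None, None)]
            all_effects = tuple(sorted({e for _, e in entries}))
            out._state[key] = replace(
                current,
                orientation=orientation,
                conflicted=False,
                effects=all_effects,
            )
    return out


def load_effect_table(path: str | Path) -> dict[tuple[int, int], str]:
    """Read a TSV of (source_entrez, target_entrez, effect)."""
    table: dict[tuple[int, int], str] = {}
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
            effect = parts[2].strip().lower()
            if effect not in (ACTIVATION, INHIBITION):
                raise ParseError(
                    f"{path}: line {lineno}: effect must be "
                    f"'{ACTIVATION}' or '{INHIBITION}', got {parts[2]!r}"
                )
            try:
                table[(int(parts[0]), int(parts[1]))] = effect
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer Entrez ID"
                ) from exc
    return table


def apply_overlay(graph: nx.Graph, overlay: DirectionOverlay) -> nx.Graph:
    """Copy ``graph`` with orientation/effect/on_path edge attributes set."""
    out = graph.copy()
    for (a, b), st in overlay.edges().items():
        if not out.has_edge(a, b):
            continue
        out.edges[a, b]["orientation"] = (
            list(st.orientation) if st.orientation else None
        )
        out.edges[a, b]["on_path"] = st.on_path
        out.edges[a, b]["conflicted"] = st.conflicted
        out.edges[a, b]["effects"] = list(st.effects)
    return out
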