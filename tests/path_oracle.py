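"""Brute-force shortest-path direction oracle, independent of networkx.

Enumerates every simple path between each (source, sink) pair by DFS,
restricts to minimum-hop paths, and tallies traversal directions per edge.
Used to cross-check the package's direction inference on small graphs.
"""

from __future__ import annotations


def _adjacency(edges):
    adj: dict = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def _all_simple_paths(adj, s, t):
    paths = []
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            paths.append(path)
            continue
        for nb in sorted(adj.get(node, ())):
            if nb not in path:
                stack.append((nb, path + [nb]))
    return paths


def _key(a, b):
    return (a, b) if a <= b else (b, a)


def oracle_directions(edges, sources, sinks, scores=None, weighted=False):
    """Expected per-edge direction state.

    Returns ``{edge_key: (orientation | None, conflicted, on_path)}`` for
    every edge.  With ``weighted=True`` only the minimum-hop path with the
    highest summed score (lexicographically smallest sequence on ties) is
    retained per (source, sink) pair.
    """
    adj = _adjacency(edges)
    traversals: dict = {}
    for s in sorted(sources):
        for t in sorted(sinks):
            if s == t:
                continue
            paths = _all_simple_paths(adj, s, t)
            if not paths:
                continue
            min_len = min(len(p) for p in paths)
            shortest = [p for p in paths if len(p) == min_len]
            if weighted:
                best_score = max(
                    sum(scores[_key(u, v)] for u, v in zip(p, p[1:]))
                    for p in shortest
                )
                shortest = [
                    min(
                        p
                        for p in shortest
                        if sum(scores[_key(u, v)] for u, v in zip(p, p[1:]))
                        == best_score
                    )
                ]
            for p in shortest:
                for u, v in zip(p, p[1:]):
                    traversals.setdefault(_key(u, v), set()).add((u, v))
    expected = {}
    for a, b in edges:
        key = _key(a, b)
        dirs = traversals.get(key, set())
        if not dirs:
            expected[key] = (None, False, False)
        elif len(dirs) == 1:
            expected[key] = (next(iter(dirs)), False, True)
        else:
            expected[key] = (None, True, True)
    return expected
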