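"""Functional and tissue annotation of interactions.

An interaction is associated with an ontology term (GO-slim term or MeSH
disease heading) when *both* interactors are directly annotated with the
term or with one of its descendants — propagation goes downward only.  A
gene is called present in a tissue/cell type when its expression is at
least 1 TPM; an interaction is assumed to take place in every context where
both interactors are present.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import NotFoundError, ParseError

#: Relation labels followed by default when closing over children.
DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})

#: Presence-call threshold in TPM ("at least one TPM"), inclusive.
DEFAULT_TPM_THRESHOLD = 1.0


class OntologyDAG:
    """A term hierarchy given as (child, parent, relation) triples.

    Supports descendant closure over a configurable set of relation labels
    (``is_a`` and ``part_of`` by default).  Construction rejects cycles.
    """

    def __init__(self, edges: Iterable[tuple[str, str, str]]):
        self.terms: set[str] = set()
        # parent -> {(child, relation)}
        self._children: dict[str, set[tuple[str, str]]] = {}
        self._parents: dict[str, set[tuple[str, str]]] = {}
        for child, parent, relation in edges:
            self.terms.add(child)
            self.terms.add(parent)
            self._children.setdefault(parent, set()).add((child, relation))
            self._parents.setdefault(child, set()).add((parent, relation))
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        WHITE, GRAY, BLACK = 0, 1, 2
        color = dict.fromkeys(self.terms, WHITE)
        for start in self.terms:
            if color[start] != WHITE:
                continue
            stack: list[tuple[str, Iterable[str]]] = [(start, iter(self._child_ids(start)))]
            color[start] = GRAY
            while stack:
                node, it = stack[-1]
                child = next(it, None)
                if child is None:
                    color[node] = BLACK
                    stack.pop()
                elif color[child] == GRAY:
                    raise ValueError(f"ontology contains a cycle through {child!r}")
                elif color[child] == WHITE:
                    color[child] = GRAY
                    stack.append((child, iter(self._child_ids(child))))

    def _child_ids(self, term: str, relations: frozenset[str] | None = None) -> list[str]:
        rels = DEFAULT_RELATIONS if relations is None else relations
        return [c for c, r in self._children.get(term, ()) if r in rels]

    def parents(self, term: str) -> set[tuple[str, str]]:
        return set(self._parents.get(term, ()))

    def descendants(
        self, term: str, relations: Iterable[str] | None = None
    ) -> set[str]:
        """Transitive closure of child terms, including ``term`` itself."""
        if term not in self.terms:
            raise NotFoundError(f"unknown ontology term {term!r}")
        rels = DEFAULT_RELATIONS if relations is None else frozenset(relations)
        seen = {term}
        frontier = [term]
        while frontier:
            node = frontier.pop()
            for child in self._child_ids(node, rels):
                if child not in seen:
                    seen.add(child)
                    frontier.append(child)
        return seen

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OntologyDAG":
        """Read a 3-column TSV (child_term, parent_term, relation)."""
        edges = []
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
                edges.append((parts[0], parts[1], parts[2]))
        return cls(edges)


def load_annotations(path: str | Path) -> dict[int, set[str]]:
    """Read a gene-term association TSV with columns (entrez, term)."""
    assignments: dict[int, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                gene = int(parts[0])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer Entrez ID {parts[0]!r}"
                ) from exc
            assignments.setdefault(gene, set()).add(parts[1])
    return assignments


def interaction_has_term(
    pair: tuple[int, int],
    annotations: Mapping[int, set[str]],
    dag: OntologyDAG,
    term: str,
    relations: Iterable[str] | None = None,
) -> bool:
    """True iff *both* interactors carry ``term`` or one of its descendants.

    A homodimer (A, A) requires only its single gene to carry the term.
    """
    closure = dag.descendants(term, relations)
    return all(
        bool(annotations.get(gene, set()) & closure) for gene in set(pair)
    )


def load_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene x context TPM matrix (TSV; first column = Entrez IDs)."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index = expr.index.astype(int)
    if (expr.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative TPM values")
    if expr.columns.duplicated().any():
        raise ParseError(f"{path}: duplicate context labels")
    return expr


def presence_calls(
    expr: pd.DataFrame, threshold: float = DEFAULT_TPM_THRESHOLD
) -> pd.DataFrame:
    """Boolean gene x context presence matrix: TPM >= threshold (inclusive)."""
    if threshold < 0:
        raise ValueError(f"TPM threshold must be nonnegative, got {threshold}")
    return expr >= threshold


def interaction_tissues(
    pair: tuple[int, int], calls: pd.DataFrame
) -> set[str]:
    """Contexts where both interactors are called present.

    Genes absent from the matrix are treated as present nowhere, so a pair
    with a missing gene has an empty tissue set.  A homodimer's tissue set
    is its gene's own presence set.
    """
    a, b = pair
    if a not in calls.index or b not in calls.index:
        return set()
    joint = calls.loc[a] & calls.loc[b]
    return set(calls.columns[joint])
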