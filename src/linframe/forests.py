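"""Rooted spanning-forest enumeration and forest-weight polynomials.

A spanning forest F of a graph G contains every vertex, has no cycles when
edge directions are ignored, and gives each vertex at most one outgoing
edge; the vertices with none are the roots.  Forests rooted at a set U,
written Phi_U(G), and their path-constrained subsets Phi_{U: j~>r}(G)
(forests containing a directed path from j to the root r) are the
combinatorial objects behind every steady-state and first-passage formula
in this package.

Enumeration assigns one outgoing edge to each non-root vertex, depth-first,
pruning any assignment that closes a cycle.  In a forest each non-root has
exactly one out-edge, so following the chain of out-edges from any vertex
reaches exactly one root — this gives the path check for free.  The cost is
bounded by the product of out-degrees; it is exact and adequate at desk
scale, but grows rapidly with graph size and density.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Union

from .algebra import Monomial, PositivePolynomial, RationalFunction
from .graph import LabeledDigraph, LabelExpr

__all__ = [
    "Forest",
    "enumerate_rooted_forests",
    "enumerate_rooted_forests_with_path",
    "forests_by_root_assignment",
    "forest_weight",
    "forest_sum",
    "evaluate",
]


@dataclass(frozen=True)
class Forest:
    """A spanning forest: an edge subset plus its root set.

    Edges are stored as (source, target, label) triples, sorted; roots as a
    frozenset.  |edges| = N - |roots| always holds for a spanning forest of
    an N-vertex graph.
    """

    edges: tuple[tuple[str, str, LabelExpr], ...]
    roots: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "edges", tuple(sorted(self.edges, key=lambda e: (e[0], e[1])))
        )

    def successor(self) -> dict[str, str]:
        """Map each non-root vertex to the target of its unique out-edge."""
        return {s: t for s, t, _ in self.edges}

    def root_of(self, v: str) -> str:
        """The root reached by following out-edges from v."""
        nxt = self.successor()
        while v in nxt:
            v = nxt[v]
        return v


def _enumerate(
    G: LabeledDigraph, roots: frozenset[str]
) -> list[Forest]:
    nonroots = [v for v in G.vertices if v not in roots]
    out = {v: sorted(G.out_edges(v), key=lambda e: e[1]) for v in nonroots}
    if any(not out[v] for v in nonroots):
        return []
    results: list[Forest] = []
    nxt: dict[str, str] = {}
    chosen: list[tuple[str, str, LabelExpr]] = []

    def closes_cycle(v: str, t: str) -> bool:
        u = t
        while u in nxt:
            u = nxt[u]
            if u == v:
                return True
        return u == v

    def recurse(k: int) -> None:
        if k == len(nonroots):
            results.append(Forest(tuple(chosen), roots))
            return
        v = nonroots[k]
        for s, t, label in out[v]:
            if closes_cycle(v, t):
                continue
            nxt[v] = t
            chosen.append((s, t, label))
            recurse(k + 1)
            chosen.pop()
            del nxt[v]

    recurse(0)
    results.sort(key=lambda f: [(s, t) for s, t, _ in f.edges])
    return results


def enumerate_rooted_forests(G: LabeledDigraph, U: Iterable[str]) -> list[Forest]:
    """All spanning forests of G rooted at U, Phi_U(G), in canonical order."""
    roots = frozenset(U)
    if not roots:
        raise ValueError("root set must be nonempty")
    for v in roots:
        G.require_vertex(v)
    return _enumerate(G, roots)


def enumerate_rooted_forests_with_path(
    G: LabeledDigraph, U: Iterable[str], j: str, r: str
) -> list[Forest]:
    """Phi_{U: j~>r}(G): forests rooted at U whose out-edge chain from j ends at r.

    The path from j to r is trivial when j = r (a root trivially reaches
    itself), so the constraint then keeps the forests in which j lies in
    r's tree — all of Phi_U(G) when j is the root r itself.
    """
    roots = frozenset(U)
    if r not in roots:
        raise ValueError(f"path target must be a root: {r!r}")
    G.require_vertex(j)
    return [F for F in enumerate_rooted_forests(G, roots) if F.root_of(j) == r]


def forests_by_root_assignment(
    G: LabeledDigraph, U: Iterable[str]
) -> dict[str, dict[str, list[Forest]]]:
    """Group Phi_U(G) by which root each vertex's chain reaches.

    Returns mapping vertex -> root -> forests; a single enumeration serves
    every path constraint over the same root set.
    """
    roots = frozenset(U)
    grouped: dict[str, dict[str, list[Forest]]] = {
        v: {r: [] for r in roots} for v in G.vertices
    }
    for F in enumerate_rooted_forests(G, roots):
        nxt = F.successor()
        root: dict[str, str] = {r: r for r in roots}
        for v in G.vertices:
            chain = []
            u = v
            while u not in root:
                chain.append(u)
                u = nxt[u]
            for c in chain:
                root[c] = root[u]
            grouped[v][root[v]].append(F)
    return grouped


def forest_weight(F: Forest) -> Monomial:
    """w(F): the product of F's edge labels; 1 for an edgeless forest."""
    atoms: tuple[str, ...] = ()
    for _, _, label in F.edges:
        atoms = atoms + label.atoms
    return Monomial(atoms, 1)


def forest_sum(forests: Iterable[Forest]) -> PositivePolynomial:
    """Sum of w(F) over a forest set; the empty set gives the zero polynomial."""
    acc: Counter = Counter()
    for F in forests:
        m = forest_weight(F)
        acc[m.atoms] += m.coefficient
    return PositivePolynomial(acc)


def evaluate(
    p: Union[PositivePolynomial, RationalFunction, Monomial],
    assignment: Mapping[str, float],
) -> float:
    """Numeric value of a polynomial, monomial or rational function."""
    return p.evaluate(assignment)
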