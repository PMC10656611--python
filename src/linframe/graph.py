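"""Labelled directed graphs and their Laplacian dynamics.

A linear-framework graph is a finite, simple, directed graph whose edges
carry labels: formal products of positive parameter symbols with the
dimensions of a rate, (time)^-1.  The graph is the infinitesimal generator
of a finite continuous-time Markov process in combinatorial form; the
Laplacian matrix L(G) drives du/dt = L(G)·u with u the column vector of
vertex probabilities.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .algebra import evaluate_atom

__all__ = [
    "LabelExpr",
    "LabeledDigraph",
    "SCCDecomposition",
    "CycleConditionResult",
    "build_graph",
    "laplacian",
    "scc_decomposition",
    "is_strongly_connected",
    "remove_outgoing_edges",
    "check_cycle_condition",
]

_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
_LITERAL_RE = re.compile(r"^\d+(\.\d+)?([eE][+-]?\d+)?$")


@dataclass(frozen=True)
class LabelExpr:
    """An edge label: a formal product of parameter symbols.

    ``atoms`` is the multiset of symbols (kept as a sorted tuple); a label
    may alternatively be a single positive decimal literal, carried as a
    literal atom.
    """

    atoms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("bad label expression: empty product")
        object.__setattr__(self, "atoms", tuple(sorted(self.atoms)))

    @classmethod
    def parse(cls, text: str) -> "LabelExpr":
        """Parse ``IDENT ('*' IDENT)*`` or a positive decimal literal."""
        text = text.strip()
        if _LITERAL_RE.match(text):
            if float(text) <= 0:
                raise ValueError(f"bad label expression: non-positive literal {text!r}")
            return cls((text,))
        parts = text.split("*")
        for p in parts:
            if not _IDENT_RE.match(p.strip()):
                raise ValueError(f"bad label expression: {text!r}")
        return cls(tuple(p.strip() for p in parts))

    def evaluate(self, assignment: Mapping[str, float]) -> float:
        value = 1.0
        for atom in self.atoms:
            value *= evaluate_atom(atom, assignment)
        return value

    def __str__(self) -> str:
        return "*".join(self.atoms)


@dataclass
class LabeledDigraph:
    """Finite simple directed graph with labelled edges.

    Vertices are strings kept in first-appearance order; at most one edge
    per ordered pair and no self-loops.
    """

    vertices: list[str] = field(default_factory=list)
    _edges: dict[tuple[str, str], LabelExpr] = field(default_factory=dict)

    # -- construction -------------------------------------------------
    def add_vertex(self, v: str) -> None:
        if v not in self._index():
            self.vertices.append(v)

    def _index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.vertices)}

    def add_edge(self, source: str, target: str, label: LabelExpr) -> None:
        if source == target:
            raise ValueError(f"self-loops forbidden: {source!r}")
        if (source, target) in self._edges:
            raise ValueError(f"parallel edge: {source!r} -> {target!r}")
        self.add_vertex(source)
        self.add_vertex(target)
        self._edges[(source, target)] = label

    # -- inspection ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.vertices)

    def edges(self) -> list[tuple[str, str, LabelExpr]]:
        return [(s, t, l) for (s, t), l in self._edges.items()]

    def has_edge(self, source: str, target: str) -> bool:
        return (source, target) in self._edges

    def label(self, source: str, target: str) -> LabelExpr:
        return self._edges[(source, target)]

    def out_edges(self, v: str) -> list[tuple[str, str, LabelExpr]]:
        return [(s, t, l) for (s, t), l in self._edges.items() if s == v]

    def atoms(self) -> set[str]:
        out: set[str] = set()
        for label in self._edges.values():
            out.update(label.atoms)
        return out

    def require_vertex(self, v: str) -> None:
        if v not in self._index():
            raise KeyError(f"no such vertex: {v!r}")

    def vertex_index(self, v: str) -> int:
        self.require_vertex(v)
        return self._index()[v]

    def copy(self) -> "LabeledDigraph":
        return LabeledDigraph(list(self.vertices), dict(self._edges))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self._edges.keys())
        return g


def build_graph(edge_records: Iterable[tuple[object, object, str]]) -> LabeledDigraph:
    """Build a graph from (source, target, label-expression-string) records.

    Vertex identifiers are coerced to strings and kept in first-appearance
    order (source before target within a record).
    """
    G = LabeledDigraph()
    for source, target, label_text in edge_records:
        G.add_edge(str(source), str(target), LabelExpr.parse(label_text))
    return G


def laplacian(G: LabeledDigraph, assignment: Mapping[str, float]) -> np.ndarray:
    """Evaluate the Laplacian matrix L(G) under a positive assignment.

    Columns index source vertices: entry (i, j), i != j, is the evaluated
    label on the edge j -> i, and each diagonal entry (j, j) is minus the
    total rate leaving j, so every column sums to zero (conservation of
    probability).
    """
    n = G.n
    L = np.zeros((n, n))
    for source, target, label in G.edges():
        rate = label.evaluate(assignment)
        j = G.vertex_index(source)
        i = G.vertex_index(target)
        L[i, j] += rate
        L[j, j] -= rate
    return L


@dataclass(frozen=True)
class SCCDecomposition:
    """Strongly connected components with their induced partial order.

    ``components`` are vertex tuples ordered by smallest contained vertex
    (in graph vertex order).  ``order`` holds the strict partial order as
    index pairs (i, j) meaning component i precedes component j, i.e. some
    directed path leaves i and enters j.  ``terminal`` lists the components
    that are maximal in the order (no outgoing edges).
    """

    components: tuple[tuple[str, ...], ...]
    order: frozenset[tuple[int, int]]
    terminal: tuple[tuple[str, ...], ...]

    def component_of(self, v: str) -> tuple[str, ...]:
        for comp in self.components:
            if v in comp:
                return comp
        raise KeyError(f"no such vertex: {v!r}")


def scc_decomposition(G: LabeledDigraph) -> SCCDecomposition:
    nxg = G.to_networkx()
    raw = [tuple(sorted(c, key=G.vertex_index)) for c in nx.strongly_connected_components(nxg)]
    comps = tuple(sorted(raw, key=lambda c: G.vertex_index(c[0])))
    which = {v: k for k, comp in enumerate(comps) for v in comp}
    direct: set[tuple[int, int]] = set()
    for s, t, _ in G.edges():
        a, b = which[s], which[t]
        if a != b:
            direct.add((a, b))
    # transitive closure of the condensation gives the partial order
    dag = nx.DiGraph()
    dag.add_nodes_from(range(len(comps)))
    dag.add_edges_from(direct)
    closure = nx.transitive_closure_dag(dag)
    order = frozenset(closure.edges())
    terminal = tuple(comps[k] for k in range(len(comps)) if dag.out_degree(k) == 0)
    return SCCDecomposition(comps, order, terminal)


def is_strongly_connected(G: LabeledDigraph) -> bool:
    return len(scc_decomposition(G).components) == 1


def remove_outgoing_edges(G: LabeledDigraph, Q: Iterable[str]) -> LabeledDigraph:
    """Copy of G lacking every edge whose source lies in Q; vertices kept."""
    Q = set(Q)
    for v in Q:
        G.require_vertex(v)
    H = LabeledDigraph(list(G.vertices), {})
    for s, t, label in G.edges():
        if s not in Q:
            H._edges[(s, t)] = label
    return H


@dataclass(frozen=True)
class CycleConditionResult:
    reversible: bool
    satisfied: bool
    worst_cycle_ratio: float


def check_cycle_condition(
    G: LabeledDigraph, assignment: Mapping[str, float], rel_tol: float = 1e-9
) -> CycleConditionResult:
    """Detailed-balance check: label-ratio products around every cycle are 1.

    A graph can reach thermodynamic equilibrium only if it is reversible
    (every edge has its reverse) and the product of forward/backward label
    ratios around every cycle equals 1.  The check runs over a cycle basis
    of the underlying undirected graph, sufficient because ratio products
    are multiplicative over the basis.
    """
    for s, t, _ in G.edges():
        if not G.has_edge(t, s):
            return CycleConditionResult(False, False, math.nan)
    und = nx.Graph()
    und.add_nodes_from(G.vertices)
    und.add_edges_from((s, t) for s, t, _ in G.edges())
    worst = 1.0
    satisfied = True
    for cycle in nx.cycle_basis(und):
        ratio = 1.0
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            ratio *= G.label(a, b).evaluate(assignment) / G.label(b, a).evaluate(assignment)
        if abs(ratio - 1.0) > rel_tol * max(1.0, abs(ratio)):
            satisfied = False
        if abs(math.log(ratio)) > abs(math.log(worst)):
            worst = ratio
    return CycleConditionResult(True, satisfied, worst)
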