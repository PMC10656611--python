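"""First-passage times, splitting probabilities and conditional FPTs.

Setting: a graph whose terminal strongly connected components are single
vertices (the targets).  Starting anywhere, the Markov process is absorbed
at a target with probability one; the moments of the first-passage time
(FPT), the splitting probability of ending at a particular target, and the
mean FPT conditioned on that outcome are all manifestly positive rational
functions of the edge labels, with numerators and denominators given by
rooted spanning-forest sums.

For a single target q and non-target set I:

* mean FPT from i:   sum_{j in I} |Phi_{{j,q}: i~>j}|_w  /  |Phi_{q}|_w
* kth moment:        k! * sum over k-tuples (j_1..j_k) in I^k of the
  product of doubly-rooted forest sums Phi_{{j_u,q}: j_{u-1}~>j_u} with
  j_0 = i, over |Phi_{q}|_w^k

where |.|_w denotes the sum of forest weights.  The k-tuple sum is computed
by dynamic programming over the matrix S[a][b] = |Phi_{{b,q}: a~>b}|_w, so
the cost is quadratic in |I| per moment order rather than |I|^k.

For several targets T, splitting probabilities and conditional means use
forests rooted at T and at T plus one non-target vertex (the formulas
below); all outputs are returned uncancelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .algebra import PositivePolynomial, RationalFunction
from .forests import forest_sum, forests_by_root_assignment
from .graph import LabeledDigraph, remove_outgoing_edges, scc_decomposition

__all__ = [
    "TargetAnalysis",
    "prepare_targets",
    "fpt_mean",
    "fpt_moment",
    "fpt_moments_value",
    "splitting_probability",
    "splitting_value",
    "conditional_mean_fpt",
    "conditional_mean_value",
    "mean_fpt_to_targets",
    "mean_to_targets_value",
    "n_min",
]

#: moments above this order use an exponential-size formula; override explicitly
DEFAULT_MAX_MOMENT = 4


@dataclass
class TargetAnalysis:
    """A graph prepared for first-passage analysis toward a target set.

    ``graph`` has had every outgoing edge of a target removed (this does
    not change the FPT distribution, since the process stops on arrival);
    each target is then a singleton terminal SCC and absorption is certain
    from every vertex.
    """

    graph: LabeledDigraph
    targets: frozenset[str]
    nonterminal: tuple[str, ...]
    _cache: dict = field(default_factory=dict, repr=False)

    def _grouped(self, roots: frozenset[str]):
        key = ("grouped", roots)
        if key not in self._cache:
            self._cache[key] = forests_by_root_assignment(self.graph, roots)
        return self._cache[key]

    def _sum(self, roots: frozenset[str], j: str | None = None, r: str | None = None):
        """Cached forest sum over Phi_roots, optionally path-constrained j~>r."""
        key = ("sum", roots, j, r)
        if key not in self._cache:
            grouped = self._grouped(roots)
            if j is None:
                # grouped[v] partitions Phi_roots by the root that v reaches,
                # so summing over any one vertex's partition covers every forest
                v0 = self.graph.vertices[0]
                self._cache[key] = forest_sum(
                    F for r_ in sorted(grouped[v0]) for F in grouped[v0][r_]
                )
            else:
                self._cache[key] = forest_sum(grouped[j][r])
        return self._cache[key]


def prepare_targets(G: LabeledDigraph, targets: Iterable[str]) -> TargetAnalysis:
    """Remove target out-edges and verify certain absorption.

    Raises if some terminal SCC of the pruned graph is not a target (the
    process could be trapped away from every target, so mean FPTs would be
    infinite).
    """
    T = frozenset(str(t) for t in targets)
    if not T:
        raise ValueError("target set must be nonempty")
    for t in T:
        G.require_vertex(t)
    H = remove_outgoing_edges(G, T)
    scc = scc_decomposition(H)
    for comp in scc.terminal:
        if set(comp) <= T:
            continue
        if len(comp) == 1:
            raise ValueError(f"unreachable target from vertex {comp[0]}")
        raise ValueError(f"absorption not certain: non-target terminal SCC {set(comp)}")
    nonterminal = tuple(v for v in H.vertices if v not in T)
    return TargetAnalysis(H, T, nonterminal)


def _single_target(A: TargetAnalysis) -> str:
    if len(A.targets) != 1:
        raise ValueError("this quantity requires a single target; see splitting/conditional FPTs")
    return next(iter(A.targets))


def _pair_sums(A: TargetAnalysis) -> dict[tuple[str, str], PositivePolynomial]:
    """S[a, b] = weight of Phi_{{b,q}: a~>b} for a, b non-target."""
    key = "pair_sums"
    if key not in A._cache:
        q = _single_target(A)
        S: dict[tuple[str, str], PositivePolynomial] = {}
        for b in A.nonterminal:
            grouped = A._grouped(frozenset({b, q}))
            for a in A.nonterminal:
                S[(a, b)] = forest_sum(grouped[a][b])
        A._cache[key] = S
    return A._cache[key]


def fpt_moment(
    A: TargetAnalysis, i: str, k: int, max_order: int = DEFAULT_MAX_MOMENT
) -> RationalFunction:
    """kth moment of the FPT from i to the single target, as a forest ratio.

    Reduces to the mean-FPT formula at k = 1.  If i is itself the target
    the FPT is identically zero and the zero rational function is returned
    (the trivial-path convention).  Orders above ``max_order`` must be
    requested explicitly; the formula's size grows quickly with k.
    """
    q = _single_target(A)
    if k < 1:
        raise ValueError("moment order must be >= 1")
    if k > max_order:
        raise ValueError(
            f"moment order {k} above cap {max_order}; pass max_order to override"
        )
    A.graph.require_vertex(i)
    den_base = A._sum(frozenset({q}))
    if i == q:
        return RationalFunction(PositivePolynomial.zero(), den_base**k)
    if i not in A.nonterminal:
        raise ValueError("start vertex is a target")
    S = _pair_sums(A)
    v = {b: S[(i, b)] for b in A.nonterminal}
    for _ in range(k - 1):
        v = {
            b: _poly_dot([v[a] for a in A.nonterminal], [S[(a, b)] for a in A.nonterminal])
            for b in A.nonterminal
        }
    numerator = PositivePolynomial.zero()
    for b in A.nonterminal:
        numerator = numerator + v[b]
    return RationalFunction(math.factorial(k) * numerator, den_base**k)


def _poly_dot(xs, ys) -> PositivePolynomial:
    acc = PositivePolynomial.zero()
    for x, y in zip(xs, ys):
        if not x.is_zero and not y.is_zero:
            acc = acc + x * y
    return acc


def fpt_mean(A: TargetAnalysis, i: str) -> RationalFunction:
    """Mean FPT from i to the single target (first moment)."""
    return fpt_moment(A, i, 1)


def fpt_moments_value(
    A: TargetAnalysis, i: str, k_max: int, assignment: Mapping[str, float]
) -> list[float]:
    """Numeric moments 1..k_max of the FPT from i, by the same forest formula.

    Forest sums are evaluated to floats before the k-tuple dynamic
    programme, which keeps high orders cheap; the symbolic route
    (:func:`fpt_moment`) produces identical values.
    """
    q = _single_target(A)
    A.graph.require_vertex(i)
    den = A._sum(frozenset({q})).evaluate(assignment)
    if i == q:
        return [0.0] * k_max
    S = {ab: p.evaluate(assignment) for ab, p in _pair_sums(A).items()}
    moments = []
    v = {b: S[(i, b)] for b in A.nonterminal}
    for k in range(1, k_max + 1):
        if k > 1:
            v = {
                b: sum(v[a] * S[(a, b)] for a in A.nonterminal)
                for b in A.nonterminal
            }
        moments.append(math.factorial(k) * sum(v.values()) / den**k)
    return moments


def splitting_probability(A: TargetAnalysis, i: str, q: str) -> RationalFunction:
    """Probability of absorption at target q rather than any other target.

    Forest ratio Phi_{T: i~>q} / Phi_T; identically 1 when i = q or when
    there is only one target, identically 0 when i is a different target.
    """
    if q not in A.targets:
        raise ValueError(f"not a target: {q!r}")
    A.graph.require_vertex(i)
    grouped = A._grouped(A.targets)
    num = forest_sum(grouped[i][q])
    den = A._sum(A.targets)
    return RationalFunction(num, den)


def conditional_mean_fpt(A: TargetAnalysis, i: str, q: str) -> RationalFunction:
    """Mean FPT from i to target q conditioned on absorption at q.

    Numerator: sum over non-target j of Phi_{T+{j}: i~>j} * Phi_{T: j~>q};
    denominator: Phi_{T: i~>q} * Phi_T.  Undefined (raises) when the
    splitting probability to q vanishes.  Equals the unconditional mean FPT
    when there is a single target.
    """
    if q not in A.targets:
        raise ValueError(f"not a target: {q!r}")
    if i in A.targets:
        raise ValueError("start vertex is a target")
    T = A.targets
    grouped_T = A._grouped(T)
    pi_num = forest_sum(grouped_T[i][q])
    if pi_num.is_zero:
        raise ValueError("target not reachable from start; conditional FPT undefined")
    num = PositivePolynomial.zero()
    for j in A.nonterminal:
        first = forest_sum(A._grouped(T | {j})[i][j])
        second = forest_sum(grouped_T[j][q])
        if not first.is_zero and not second.is_zero:
            num = num + first * second
    den = pi_num * A._sum(T)
    return RationalFunction(num, den)


def mean_fpt_to_targets(A: TargetAnalysis, i: str) -> RationalFunction:
    """Unconditional mean FPT from i to the target set.

    Equals sum_q pi_{i,q} * chi_{i,q} and specialises to the single-target
    mean FPT when |T| = 1.
    """
    if i in A.targets:
        raise ValueError("start vertex is a target")
    num = PositivePolynomial.zero()
    for j in A.nonterminal:
        num = num + forest_sum(A._grouped(A.targets | {j})[i][j])
    return RationalFunction(num, A._sum(A.targets))


def splitting_value(
    A: TargetAnalysis, i: str, q: str, assignment: Mapping[str, float]
) -> float:
    """Numeric splitting probability (forest sums evaluated before dividing)."""
    if q not in A.targets:
        raise ValueError(f"not a target: {q!r}")
    num = A._sum(A.targets, i, q).evaluate(assignment)
    return num / A._sum(A.targets).evaluate(assignment)


def conditional_mean_value(
    A: TargetAnalysis, i: str, q: str, assignment: Mapping[str, float]
) -> float:
    """Numeric conditional mean FPT by the same forest formula as
    :func:`conditional_mean_fpt`, combining evaluated forest sums."""
    if q not in A.targets:
        raise ValueError(f"not a target: {q!r}")
    pi_num = A._sum(A.targets, i, q).evaluate(assignment)
    if pi_num == 0:
        raise ValueError("target not reachable from start; conditional FPT undefined")
    num = sum(
        A._sum(A.targets | {j}, i, j).evaluate(assignment)
        * A._sum(A.targets, j, q).evaluate(assignment)
        for j in A.nonterminal
    )
    return num / (pi_num * A._sum(A.targets).evaluate(assignment))


def mean_to_targets_value(
    A: TargetAnalysis, i: str, assignment: Mapping[str, float]
) -> float:
    """Numeric unconditional mean FPT to the target set."""
    num = sum(
        A._sum(A.targets | {j}, i, j).evaluate(assignment) for j in A.nonterminal
    )
    return num / A._sum(A.targets).evaluate(assignment)


def n_min(A: TargetAnalysis, i: str, assignment: Mapping[str, float]) -> float:
    """Reciprocal squared coefficient of variation of the FPT, mean^2/variance.

    Interpreted as the minimum number of hidden states consistent with the
    observed FPT statistics; always strictly below the number of graph
    vertices.
    """
    m1, m2 = fpt_moments_value(A, i, 2, assignment)
    var = m2 - m1 * m1
    if var <= 0:
        raise ValueError("zero variance")
    return m1 * m1 / var
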