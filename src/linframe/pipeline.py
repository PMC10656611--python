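"""Closed-form enzyme kinetics on pipeline graphs.

A pipeline graph is a nearest-neighbour chain of enzyme conformations
1, ..., N with forward rates p_1..p_{N-1} and backward rates q_1..q_{N-2};
the final catalytic transition N-1 -> N is irreversible.  Substrate binds
(reversibly) at a subset of the forward transitions, multiplying those
labels by the concentration x.  Irreversible transitions partition the
chain into reversible blocks.

For a single reversible block the mean completion time has the closed form

    tau = sum_{j=1..N-1} Delta(j, N) / p_j,
    Delta(j, N) = sum_{k=j+1..N} prod_{u=j..k-2} q_u / p_{u+1},

with the empty product (k = j+1) equal to 1.  As a function of x the
completion time is (a_0 + a_1 x + ... + a_s x^s) / (b x^s) with s the
number of binding transitions; s = 1 is the reciprocal Michaelis-Menten
form.  For multiple blocks the FPTs of the blocks are independent and
moments add: the mean is the sum of block means and the second moment
picks up the cross terms 2 * sum_{i<j} tau_i tau_j.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .algebra import PositivePolynomial, RationalFunction, evaluate_atom
from .graph import LabeledDigraph, LabelExpr

__all__ = [
    "PipelineSpec",
    "ConcentrationProfile",
    "CompletionTime",
    "build_pipeline",
    "delta",
    "pipeline_mean_fpt",
    "concentration_profile",
    "block_decompose",
    "combine_block_moments",
]


@dataclass(frozen=True)
class PipelineSpec:
    """Parametric description of a (possibly multi-block) pipeline.

    ``forward[i-1]`` names the label of i -> i+1; ``backward[i-1]`` names
    the label of i+1 -> i or is None for an irreversible transition (the
    final transition N-1 -> N is irreversible by construction and has no
    backward entry).  ``binding_sites`` are the 1-based forward transitions
    whose label carries the concentration symbol; they must be reversible,
    which excludes the final catalytic transition.
    """

    n: int
    forward: tuple[str, ...]
    backward: tuple[str | None, ...]
    binding_sites: frozenset[int] = frozenset()
    conc: str = "x"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("pipeline needs at least 2 vertices")
        if len(self.forward) != self.n - 1:
            raise ValueError("need one forward label per transition")
        if len(self.backward) != self.n - 2:
            raise ValueError("need one backward entry per non-final transition")
        for s in self.binding_sites:
            if not 1 <= s <= self.n - 2:
                raise ValueError("binding sites exclude the final catalytic transition")
            if self.backward[s - 1] is None:
                raise ValueError("substrate binding must be reversible")

    @classmethod
    def create(
        cls,
        n: int,
        binding_sites: Sequence[int] = (),
        irreversible: Sequence[int] = (),
        conc: str = "x",
    ) -> "PipelineSpec":
        """Spec with default names p1..p_{n-1}, q1..q_{n-2}.

        ``irreversible`` lists intermediate transitions (1-based, < n-1)
        lacking the backward edge.
        """
        forward = tuple(f"p{i}" for i in range(1, n))
        backward = tuple(
            None if i in set(irreversible) else f"q{i}" for i in range(1, n - 1)
        )
        return cls(n, forward, backward, frozenset(binding_sites), conc)

    # -- structure ----------------------------------------------------
    def is_irreversible(self, i: int) -> bool:
        """Whether forward transition i (1-based) lacks its reverse."""
        return i == self.n - 1 or self.backward[i - 1] is None

    def block_starts(self) -> list[int]:
        """Vertices e_0 < e_1 < ... starting each reversible block."""
        starts = [1]
        for i in range(1, self.n - 1):
            if self.is_irreversible(i):
                starts.append(i + 1)
        return starts

    def forward_label(self, i: int) -> LabelExpr:
        atoms: tuple[str, ...] = (self.forward[i - 1],)
        if i in self.binding_sites:
            atoms = atoms + (self.conc,)
        return LabelExpr(atoms)

    @property
    def single_block(self) -> bool:
        return len(self.block_starts()) == 1


def build_pipeline(spec: PipelineSpec) -> LabeledDigraph:
    """The pipeline's labelled digraph, vertices "1".."N"."""
    G = LabeledDigraph()
    for v in range(1, spec.n + 1):
        G.add_vertex(str(v))
    for i in range(1, spec.n):
        G.add_edge(str(i), str(i + 1), spec.forward_label(i))
        if not spec.is_irreversible(i):
            G.add_edge(str(i + 1), str(i), LabelExpr((spec.backward[i - 1],)))
    return G


def _ratio_atom(spec: PipelineSpec, u: int) -> str:
    """Formal ratio q_u / p_{u+1}, with the concentration folded into p."""
    p = spec.forward[u]  # forward transition u+1
    if (u + 1) in spec.binding_sites:
        p = f"{p}*{spec.conc}"
    q = spec.backward[u - 1]
    assert q is not None
    return f"{q}/{p}"


def delta(spec: PipelineSpec, j: int) -> PositivePolynomial:
    """Delta(j, N): the backward-ratio sum of the single-block completion time.

    A polynomial over formal ratio atoms q_u/p_{u+1} with N - j terms; the
    k = j+1 term is the empty product 1.
    """
    if not spec.single_block:
        raise ValueError("use block_decompose")
    if not 1 <= j <= spec.n - 1:
        raise ValueError(f"index out of range: j={j}")
    total = PositivePolynomial.zero()
    for k in range(j + 1, spec.n + 1):
        atoms = tuple(_ratio_atom(spec, u) for u in range(j, k - 1))
        total = total + PositivePolynomial.from_atoms(atoms)
    return total


@dataclass(frozen=True)
class CompletionTime:
    """Symbolic completion time: sum over j of Delta(j, N) / (forward label j)."""

    terms: tuple[tuple[LabelExpr, PositivePolynomial], ...]

    def evaluate(self, assignment: Mapping[str, float]) -> float:
        return sum(
            d.evaluate(assignment) / label.evaluate(assignment)
            for label, d in self.terms
        )

    def __str__(self) -> str:
        return " + ".join(f"({d}) / {label}" for label, d in self.terms)


def pipeline_mean_fpt(spec: PipelineSpec) -> CompletionTime:
    """Mean completion time of a single-block pipeline, in closed form.

    Numerically identical to the forest-sum mean FPT on the built graph
    for every positive assignment.
    """
    if not spec.single_block:
        raise ValueError("use block_decompose")
    return CompletionTime(
        tuple((spec.forward_label(j), delta(spec, j)) for j in range(1, spec.n))
    )


@dataclass(frozen=True)
class ConcentrationProfile:
    """rf collected as (a_0 + a_1 x + ... + a_s x^s) / (b x^s)."""

    a: tuple[PositivePolynomial, ...]
    b: PositivePolynomial
    s: int

    def evaluate(self, x_value: float, assignment: Mapping[str, float]) -> float:
        num = sum(
            ai.evaluate(assignment) * x_value**d for d, ai in enumerate(self.a)
        )
        return num / (self.b.evaluate(assignment) * x_value**self.s)


def _split_power(terms: Mapping[tuple[str, ...], int], x: str):
    by_power: dict[int, dict[tuple[str, ...], int]] = {}
    for atoms, coeff in terms.items():
        d = sum(1 for a in atoms if a == x)
        stripped = tuple(a for a in atoms if a != x)
        by_power.setdefault(d, {})[stripped] = (
            by_power.get(d, {}).get(stripped, 0) + coeff
        )
    return by_power


def concentration_profile(rf: RationalFunction, x: str = "x") -> ConcentrationProfile:
    """Collect a completion-time rational function by powers of concentration.

    Requires the pipeline shape: every denominator term carries the same
    power x^s and the numerator has degree at most s in x, with a nonzero
    leading coefficient a_s (the forest containing all binding transitions
    guarantees this for pipelines).  The completion time then diverges like
    x^{-s} at low substrate and asymptotes to a_s / b at high substrate.
    """
    den_powers = _split_power(rf.denominator.terms, x)
    if len(den_powers) != 1:
        raise ValueError("not x-collectable: denominator is not a monomial in x")
    s = next(iter(den_powers))
    b = PositivePolynomial(den_powers[s])
    num_powers = _split_power(rf.numerator.terms, x)
    if any(d > s for d in num_powers):
        raise ValueError("not x-collectable: numerator degree exceeds denominator")
    a = tuple(
        PositivePolynomial(num_powers.get(d, {})) for d in range(s + 1)
    )
    if s > 0 and a[s].is_zero:
        raise ValueError("not x-collectable: vanishing leading coefficient")
    return ConcentrationProfile(a, b, s)


def block_decompose(spec: PipelineSpec) -> list[PipelineSpec]:
    """Split a pipeline at its irreversible transitions into single blocks.

    Block i spans vertices e_{i-1}..e_i and keeps the original label names;
    a single-block spec decomposes into itself.  The process takes each
    irreversible transition exactly once, so the block FPTs are independent
    and their moments combine by :func:`combine_block_moments`.
    """
    starts = spec.block_starts()
    ends = starts[1:] + [spec.n]
    blocks = []
    for e_prev, e in zip(starts, ends):
        nb = e - e_prev + 1
        forward = tuple(spec.forward[g - 1] for g in range(e_prev, e))
        backward = tuple(spec.backward[g - 1] for g in range(e_prev, e - 1))
        binding = frozenset(
            g - e_prev + 1 for g in spec.binding_sites if e_prev <= g <= e - 1
        )
        blocks.append(PipelineSpec(nb, forward, backward, binding, spec.conc))
    return blocks


def combine_block_moments(block_moments: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Combine independent per-block (mean, second moment) into full-chain moments.

    Mean adds; the second moment adds with cross terms from independence:
    m2 = sum_i m2_i + 2 * sum_{i<j} m1_i m1_j.
    """
    means = [m1 for m1, _ in block_moments]
    mean = sum(means)
    second = sum(m2 for _, m2 in block_moments)
    for i in range(len(means)):
        for j in range(i + 1, len(means)):
            second += 2 * means[i] * means[j]
    return mean, second
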