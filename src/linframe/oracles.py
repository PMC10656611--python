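"""Independent ground-truth engines for validating the forest formulas.

Nothing here touches spanning forests (except the brute-force edge-subset
search, which deliberately ignores the enumeration engine): steady states
come from the Laplacian null space, FPT moments from the absorbed-chain
linear systems, splitting probabilities and conditional means from the
first-step absorption systems, transient distributions from the matrix
exponential, and empirical statistics from Gillespie-style trajectory
simulation.  Agreement between these engines and the graph formulas is the
package's core correctness argument.

Convention: the Laplacian here has zero column sums (columns index source
vertices), so the row-convention generator used in the linear systems is
its transpose.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.linalg

from .forests import Forest
from .graph import LabeledDigraph, laplacian
from .transient import TargetAnalysis

__all__ = [
    "SimResult",
    "oracle_steady_state",
    "oracle_fpt_moments",
    "oracle_absorption",
    "brute_force_forests",
    "propagate_master_equation",
    "simulate",
]


def oracle_steady_state(G: LabeledDigraph, assignment: Mapping[str, float]) -> np.ndarray:
    """Stationary distribution as the normalised null vector of L(G)."""
    L = laplacian(G, assignment)
    _, s, vt = np.linalg.svd(L)
    tol = max(L.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
    null_dim = int(np.sum(s <= max(tol, 1e-10 * s[0])))
    if null_dim != 1:
        raise ValueError("kernel dimension != 1")
    v = vt[-1]
    v = v / v.sum()
    if not np.all(v > 0):
        raise ValueError("kernel vector is not strictly positive")
    return v


def _restricted_generator(
    A: TargetAnalysis, assignment: Mapping[str, float]
) -> tuple[np.ndarray, list[str]]:
    """Row-convention generator restricted to the non-target vertices."""
    G = A.graph
    L = laplacian(G, assignment)
    Q = L.T  # rows index source vertices
    idx = [G.vertex_index(v) for v in A.nonterminal]
    return Q[np.ix_(idx, idx)], list(A.nonterminal)


def oracle_fpt_moments(
    A: TargetAnalysis, i: str, k_max: int, assignment: Mapping[str, float]
) -> list[float]:
    """FPT moments 1..k_max by the absorbed-chain recursion.

    With A the generator restricted to the non-target vertices, the moment
    vectors satisfy (-A) m^(k) = k m^(k-1), m^(0) = 1.
    """
    q, nonterminal = _restricted_generator(A, assignment)
    if i in A.targets:
        return [0.0] * k_max
    pos = nonterminal.index(i)
    m_prev = np.ones(len(nonterminal))
    out = []
    for k in range(1, k_max + 1):
        try:
            m = np.linalg.solve(-q, k * m_prev)
        except np.linalg.LinAlgError as exc:
            raise ValueError("target unreachable") from exc
        out.append(float(m[pos]))
        m_prev = m
    return out


def oracle_absorption(
    A: TargetAnalysis, i: str, assignment: Mapping[str, float]
) -> tuple[dict[str, float], dict[str, float]]:
    """Splitting probabilities and conditional mean FPTs by first-step systems.

    For each target t, the hitting probabilities h solve A h + r_t = 0 with
    r_t the rate vector into t; the products eta = h * chi solve
    (-A) eta = h.  Returns ({target: pi}, {target: chi}); chi is omitted
    for targets with pi = 0.
    """
    Q, nonterminal = _restricted_generator(A, assignment)
    G = A.graph
    pis: dict[str, float] = {}
    chis: dict[str, float] = {}
    for t in sorted(A.targets):
        if i in A.targets:
            pis[t] = 1.0 if i == t else 0.0
            continue
        r = np.zeros(len(nonterminal))
        for s, tgt, label in G.edges():
            if tgt == t and s in nonterminal:
                r[nonterminal.index(s)] += label.evaluate(assignment)
        h = np.linalg.solve(-Q, r)
        eta = np.linalg.solve(-Q, h)
        pos = nonterminal.index(i)
        pis[t] = float(h[pos])
        if h[pos] > 0:
            chis[t] = float(eta[pos] / h[pos])
    return pis, chis


def brute_force_forests(
    G: LabeledDigraph,
    U: Iterable[str],
    path_constraint: tuple[str, str] | None = None,
) -> list[Forest]:
    """All rooted spanning forests by filtering raw edge subsets.

    Checks every C(|E|, N - |U|) subset against the forest invariants; an
    equivalence oracle for the enumeration engine, guarded to small graphs.
    """
    roots = frozenset(U)
    edges = G.edges()
    if len(edges) > 20:
        raise ValueError("oracle guard exceeded: more than 20 edges")
    size = G.n - len(roots)
    found = []
    for subset in itertools.combinations(edges, size):
        sources = [s for s, _, _ in subset]
        if len(set(sources)) != len(sources):
            continue  # a vertex with two out-edges
        if any(s in roots for s in sources):
            continue
        if set(sources) != {v for v in G.vertices if v not in roots}:
            continue
        # acyclic when directions are ignored <=> functional chains end at roots
        nxt = {s: t for s, t, _ in subset}
        ok = True
        for v in nxt:
            seen = set()
            u = v
            while u in nxt:
                if u in seen:
                    ok = False
                    break
                seen.add(u)
                u = nxt[u]
            if not ok:
                break
        if not ok:
            continue
        F = Forest(tuple(subset), roots)
        if path_constraint is not None:
            j, r = path_constraint
            if F.root_of(j) != r:
                continue
        found.append(F)
    found.sort(key=lambda f: [(s, t) for s, t, _ in f.edges])
    return found


def propagate_master_equation(
    G: LabeledDigraph,
    u0: Sequence[float],
    t: float,
    assignment: Mapping[str, float],
) -> np.ndarray:
    """exp(t L) u0: the vertex-probability vector after time t."""
    u0 = np.asarray(u0, dtype=float)
    if abs(u0.sum() - 1.0) > 1e-10:
        raise ValueError("initial distribution must sum to 1")
    L = laplacian(G, assignment)
    return scipy.linalg.expm(t * L) @ u0


@dataclass(frozen=True)
class SimResult:
    """Empirical first-passage statistics from stochastic simulation."""

    n_trajectories: int
    seed: int
    splitting: dict[str, float]
    splitting_se: dict[str, float]
    mean_fpt: float
    mean_fpt_se: float
    second_moment_fpt: float
    conditional_mean: dict[str, float]
    conditional_mean_se: dict[str, float]


def simulate(
    A: TargetAnalysis,
    start: str,
    n_traj: int,
    seed: int,
    assignment: Mapping[str, float],
    max_jumps: int = 10**6,
) -> SimResult:
    """Gillespie simulation of the absorbed process from ``start``.

    Exponential waiting times with the total exit rate, categorical jumps
    proportional to the edge labels, stopping on first entry to a target.
    Reproducible for a fixed seed.
    """
    if n_traj < 1:
        raise ValueError("need at least one trajectory")
    G = A.graph
    rng = np.random.default_rng(seed)
    out_rates: dict[str, tuple[list[str], np.ndarray, float]] = {}
    for v in A.nonterminal:
        edges = G.out_edges(v)
        targets = [t for _, t, _ in edges]
        rates = np.array([l.evaluate(assignment) for _, _, l in edges])
        out_rates[v] = (targets, rates / rates.sum(), float(rates.sum()))
    times = np.empty(n_traj)
    hits: list[str] = []
    for n in range(n_traj):
        v = start
        t = 0.0
        for _ in range(max_jumps):
            if v in A.targets:
                break
            targets, probs, total = out_rates[v]
            t += rng.exponential(1.0 / total)
            v = targets[rng.choice(len(targets), p=probs)]
        else:
            raise RuntimeError("nonabsorbing trajectory guard")
        times[n] = t
        hits.append(v)
    hits_arr = np.array(hits)
    splitting = {}
    splitting_se = {}
    cond_mean = {}
    cond_se = {}
    for q in sorted(A.targets):
        mask = hits_arr == q
        p = float(mask.mean())
        splitting[q] = p
        splitting_se[q] = float(np.sqrt(p * (1 - p) / n_traj))
        if mask.sum() > 1:
            cond_mean[q] = float(times[mask].mean())
            cond_se[q] = float(times[mask].std(ddof=1) / np.sqrt(mask.sum()))
    return SimResult(
        n_trajectories=n_traj,
        seed=seed,
        splitting=splitting,
        splitting_se=splitting_se,
        mean_fpt=float(times.mean()),
        mean_fpt_se=float(times.std(ddof=1) / np.sqrt(n_traj)),
        second_moment_fpt=float((times**2).mean()),
        conditional_mean=cond_mean,
        conditional_mean_se=cond_se,
    )
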