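"""Cross-validation sweep: forest formulas vs linear-algebra oracles.

Runs seeded random strongly connected graphs through both computational
routes — rooted-forest formulas on one side, Laplacian null-space /
absorbed-chain / first-step linear systems on the other — and records the
worst relative disagreement per quantity.  Forest sums are evaluated
numerically before being combined, which the unit suite verifies is
identical to the fully symbolic route.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import oracles, transient
from .fixtures import random_graph
from .steady import steady_state

__all__ = ["CrossValidationReport", "cross_validate"]


def _rel(a: float, b: float) -> float:
    return abs(a - b) / max(abs(a), abs(b), 1e-300)


@dataclass
class CrossValidationReport:
    n_graphs: int
    n_assignments: int
    seed: int
    max_rel_error: dict[str, float] = field(default_factory=dict)
    n_min_max: float = 0.0
    n_min_bound_ok: bool = True

    def passed(self, tol: float = 1e-9) -> bool:
        return all(v <= tol for v in self.max_rel_error.values()) and self.n_min_bound_ok

    def table(self) -> str:
        lines = [f"{'quantity':32s} {'max rel err':>12s}"]
        for k, v in sorted(self.max_rel_error.items()):
            lines.append(f"{k:32s} {v:12.3e}")
        lines.append(f"n_min bound (< N) held: {self.n_min_bound_ok}")
        return "\n".join(lines)


def _record(report: CrossValidationReport, key: str, err: float) -> None:
    report.max_rel_error[key] = max(report.max_rel_error.get(key, 0.0), err)


def cross_validate(
    n_graphs: int = 100,
    seed: int = 0,
    n_assignments: int = 3,
    k_max: int = 3,
    n_max: int = 7,
) -> CrossValidationReport:
    """Compare every forest formula against its oracle on random graphs.

    Per graph: the stationary distribution, single-target FPT moments up to
    ``k_max``, splitting probabilities, conditional mean FPTs, the
    unconditional mean to the target set and its identity with
    sum_q pi * chi, plus the n_min < N bound.
    """
    rng = np.random.default_rng(seed)
    report = CrossValidationReport(n_graphs, n_assignments, seed)
    for g in range(n_graphs):
        n = int(rng.integers(3, n_max + 1))
        extra = int(rng.integers(1, min(n + 2, n * (n - 2) + 1)))
        G = random_graph(n, extra, seed=int(rng.integers(0, 2**31 - 1)))
        atoms = sorted(G.atoms())
        verts = G.vertices
        q_single = verts[-1]
        A1 = transient.prepare_targets(G, {q_single})
        pair = [verts[-1], verts[-2]]
        A2 = transient.prepare_targets(G, pair)
        ss = steady_state(G)
        for _ in range(n_assignments):
            assignment: Mapping[str, float] = {
                a: float(rng.uniform(0.2, 3.0)) for a in atoms
            }
            # stationary distribution vs Laplacian null space
            u = oracles.oracle_steady_state(G, assignment)
            for comp, target in zip(ss, u):
                _record(report, "steady_state", _rel(comp.evaluate(assignment), target))
            # FPT moments vs absorbed-chain linear systems
            i = verts[0]
            mine = transient.fpt_moments_value(A1, i, k_max, assignment)
            ref = oracles.oracle_fpt_moments(A1, i, k_max, assignment)
            for k, (m, r) in enumerate(zip(mine, ref), start=1):
                _record(report, f"fpt_moment_k{k}", _rel(m, r))
            # n_min bound
            nm = transient.n_min(A1, i, assignment)
            report.n_min_max = max(report.n_min_max, nm / n)
            if not nm < n:
                report.n_min_bound_ok = False
            # splitting / conditional / unconditional vs first-step systems
            pis, chis = oracles.oracle_absorption(A2, i, assignment)
            psi_combined = 0.0
            for q in pair:
                pi_mine = transient.splitting_value(A2, i, q, assignment)
                _record(report, "splitting_probability", _rel(pi_mine, pis[q]))
                if q in chis and pis[q] > 1e-12:
                    chi_mine = transient.conditional_mean_value(A2, i, q, assignment)
                    _record(report, "conditional_mean_fpt", _rel(chi_mine, chis[q]))
                    psi_combined += pis[q] * chis[q]
            psi_mine = transient.mean_to_targets_value(A2, i, assignment)
            _record(report, "mean_fpt_to_targets", _rel(psi_mine, psi_combined))
    return report
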