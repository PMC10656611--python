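"""First-passage moments, splitting probabilities and conditional means."""

import math

import numpy as np
import pytest

from linframe import (
    build_graph,
    conditional_mean_fpt,
    fixture,
    fpt_mean,
    fpt_moment,
    mean_fpt_to_targets,
    n_min,
    prepare_targets,
    splitting_probability,
)
from linframe.oracles import oracle_absorption, oracle_fpt_moments
from linframe.transient import fpt_moments_value


class TestPrepareTargets:
    def test_absorbing_example(self, fig2, fig3):
        A = prepare_targets(fig2, {"5"})
        assert sorted((s, t) for s, t, _ in A.graph.edges()) == sorted(
            (s, t) for s, t, _ in fig3.edges()
        )
        assert set(A.nonterminal) == {"1", "2", "3", "4"}

    def test_two_targets(self, fig4):
        A = prepare_targets(fig4, {"5", "6"})
        assert set(A.nonterminal) == {"1", "2", "3", "4"}

    def test_unreachable_target(self):
        G = build_graph([(1, 2, "a"), (3, 4, "b")])
        with pytest.raises(ValueError, match="unreachable target"):
            prepare_targets(G, {"2"})

    def test_non_target_trap(self):
        # 3 <-> 4 is a trap the process can enter instead of the target
        G = build_graph([(1, 2, "a"), (1, 3, "b"), (3, 4, "c"), (4, 3, "d")])
        with pytest.raises(ValueError, match="absorption not certain"):
            prepare_targets(G, {"2"})


class TestFPTMoments:
    def test_two_state_closed_form(self, two_state):
        A = prepare_targets(two_state, {"2"})
        for k in range(1, 5):
            rf = fpt_moment(A, "1", k)
            assert rf.numerator.terms == {(): math.factorial(k)}
            assert rf.denominator.terms == {("a",) * k: 1}

    def test_chain_mean(self, chain_ab):
        A = prepare_targets(chain_ab, {"3"})
        rf = fpt_mean(A, "1")
        assert str(rf) == "(a + b) / (a*b)"
        a, b = 1.3, 0.4
        assert rf.evaluate({"a": a, "b": b}) == pytest.approx(1 / a + 1 / b)

    def test_chain_second_moment(self, chain_ab):
        A = prepare_targets(chain_ab, {"3"})
        assert fpt_moment(A, "1", 2).evaluate({"a": 1, "b": 1}) == pytest.approx(6.0)

    def test_moment_one_equals_mean(self, fig3):
        A = prepare_targets(fig3, {"5"})
        assert fpt_moment(A, "1", 1) == fpt_mean(A, "1")

    def test_worked_example_numerator(self, fig3):
        A = prepare_targets(fig3, {"5"})
        assert fpt_mean(A, "1").numerator.num_terms() == 24

    def test_same_on_strong_and_absorbing_graph(self, fig2, fig3, make_assignment):
        A2 = prepare_targets(fig2, {"5"})
        A3 = prepare_targets(fig3, {"5"})
        assignment = make_assignment(fig2)
        for k in (1, 2):
            assert fpt_moment(A2, "1", k).evaluate(assignment) == pytest.approx(
                fpt_moment(A3, "1", k).evaluate(assignment)
            )

    def test_start_equals_target_is_zero(self, two_state):
        A = prepare_targets(two_state, {"2"})
        assert fpt_moment(A, "2", 1).numerator.is_zero

    def test_moment_order_validation(self, two_state):
        A = prepare_targets(two_state, {"2"})
        with pytest.raises(ValueError, match="moment order must be >= 1"):
            fpt_moment(A, "1", 0)
        with pytest.raises(ValueError, match="above cap"):
            fpt_moment(A, "1", 5)
        assert fpt_moment(A, "1", 5, max_order=5).evaluate({"a": 1, "b": 1}) == pytest.approx(120)

    def test_dimension_grading(self, fig3):
        """Numerator degree is k less than denominator degree: (time)^k."""
        A = prepare_targets(fig3, {"5"})
        for k in (1, 2):
            rf = fpt_moment(A, "1", k)
            num_deg = {len(atoms) for atoms in rf.numerator.terms}
            den_deg = {len(atoms) for atoms in rf.denominator.terms}
            assert num_deg == {k * (A.graph.n - 2)}
            assert den_deg == {k * (A.graph.n - 1)}

    def test_jensen_and_oracle(self, fig3, make_assignment):
        A = prepare_targets(fig3, {"5"})
        assignment = make_assignment(fig3)
        mine = fpt_moments_value(A, "1", 3, assignment)
        ref = oracle_fpt_moments(A, "1", 3, assignment)
        assert mine == pytest.approx(ref, rel=1e-12)
        assert mine[1] >= mine[0] ** 2
        # symbolic route agrees with the numeric route
        for k in (1, 2, 3):
            rf = fpt_moment(A, "1", k)
            assert rf.evaluate(assignment) == pytest.approx(mine[k - 1], rel=1e-12)


class TestSplitting:
    def test_worked_example_counts(self, fig4):
        A = prepare_targets(fig4, {"5", "6"})
        pi = splitting_probability(A, "1", "5")
        assert pi.numerator.num_terms() == 6
        assert pi.denominator.num_terms() == 18

    def test_fork_values(self, fork):
        A = prepare_targets(fork, {"2", "3"})
        assert splitting_probability(A, "1", "2").evaluate({"a": 2, "b": 1}) == pytest.approx(2 / 3)

    def test_degenerate_starts(self, fig4):
        A = prepare_targets(fig4, {"5", "6"})
        assignment = {s: 1.0 for s in fig4.atoms()}
        assert splitting_probability(A, "5", "5").evaluate(assignment) == 1.0
        assert splitting_probability(A, "6", "5").evaluate(assignment) == 0.0

    def test_single_target_gives_one(self, fig3):
        A = prepare_targets(fig3, {"5"})
        pi = splitting_probability(A, "2", "5")
        assert pi.numerator == pi.denominator

    def test_sums_to_one_and_in_range(self, fig4, make_assignment):
        A = prepare_targets(fig4, {"5", "6"})
        for _ in range(5):
            assignment = make_assignment(fig4)
            values = [
                splitting_probability(A, "1", q).evaluate(assignment) for q in ("5", "6")
            ]
            assert all(0 <= v <= 1 for v in values)
            assert sum(values) == pytest.approx(1.0, rel=1e-12)

    def test_non_target_rejected(self, fig4):
        A = prepare_targets(fig4, {"5", "6"})
        with pytest.raises(ValueError, match="not a target"):
            splitting_probability(A, "1", "2")


class TestConditionalFPT:
    def test_fork_closed_form(self, fork):
        A = prepare_targets(fork, {"2", "3"})
        a, b = 2.0, 1.0
        chi = conditional_mean_fpt(A, "1", "2")
        assert chi.evaluate({"a": a, "b": b}) == pytest.approx(1 / (a + b))
        # symmetric rates give symmetric conditional means
        sym = {"a": 1.4, "b": 1.4}
        assert conditional_mean_fpt(A, "1", "2").evaluate(sym) == pytest.approx(
            conditional_mean_fpt(A, "1", "3").evaluate(sym)
        )

    def test_single_target_equals_mean(self, fig3, make_assignment):
        A = prepare_targets(fig3, {"5"})
        assignment = make_assignment(fig3)
        assert conditional_mean_fpt(A, "1", "5").evaluate(assignment) == pytest.approx(
            fpt_mean(A, "1").evaluate(assignment), rel=1e-12
        )

    def test_matches_absorption_oracle(self, fig4, make_assignment):
        A = prepare_targets(fig4, {"5", "6"})
        assignment = make_assignment(fig4)
        pis, chis = oracle_absorption(A, "1", assignment)
        for q in ("5", "6"):
            assert splitting_probability(A, "1", q).evaluate(assignment) == pytest.approx(
                pis[q], rel=1e-9
            )
            assert conditional_mean_fpt(A, "1", q).evaluate(assignment) == pytest.approx(
                chis[q], rel=1e-9
            )

    def test_unreachable_target_rejected(self):
        G = build_graph([(1, 2, "a"), (3, 2, "b"), (3, 4, "c")])
        A = prepare_targets(G, {"2", "4"})
        with pytest.raises(ValueError, match="conditional FPT undefined"):
            conditional_mean_fpt(A, "1", "4")


class TestMeanToTargets:
    def test_fork_exit_time(self, fork):
        A = prepare_targets(fork, {"2", "3"})
        psi = mean_fpt_to_targets(A, "1")
        a, b = 0.9, 2.2
        assert psi.evaluate({"a": a, "b": b}) == pytest.approx(1 / (a + b))

    def test_specialises_to_single_target_mean(self, fig3):
        A = prepare_targets(fig3, {"5"})
        assert mean_fpt_to_targets(A, "1") == fpt_mean(A, "1")

    def test_decomposes_over_targets(self, fig4, make_assignment):
        A = prepare_targets(fig4, {"5", "6"})
        assignment = make_assignment(fig4)
        combined = sum(
            splitting_probability(A, "1", q).evaluate(assignment)
            * conditional_mean_fpt(A, "1", q).evaluate(assignment)
            for q in ("5", "6")
        )
        assert mean_fpt_to_targets(A, "1").evaluate(assignment) == pytest.approx(
            combined, rel=1e-9
        )


class TestNMin:
    def test_two_state(self, two_state):
        A = prepare_targets(two_state, {"2"})
        assert n_min(A, "1", {"a": 0.7, "b": 9.0}) == pytest.approx(1.0)

    def test_erlang_two_stages(self):
        G = build_graph([(1, 2, "r"), (2, 3, "r")])
        A = prepare_targets(G, {"3"})
        assert n_min(A, "1", {"r": 3.0}) == pytest.approx(2.0)

    def test_below_vertex_count_on_fixtures(self, fig3, make_assignment):
        A = prepare_targets(fig3, {"5"})
        for _ in range(5):
            assert n_min(A, "1", make_assignment(fig3)) < fig3.n
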