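"""Graph model, Laplacian, SCC machinery and the detailed-balance check."""

import math

import numpy as np
import pytest

from linframe import (
    build_graph,
    check_cycle_condition,
    fixture,
    is_strongly_connected,
    laplacian,
    remove_outgoing_edges,
    scc_decomposition,
)
from linframe.pipeline import build_pipeline


class TestBuildGraph:
    def test_two_vertex(self, two_state):
        assert two_state.n == 2
        assert len(two_state.edges()) == 2

    def test_ligand_binding_square(self):
        G = fixture("fig1_square")
        assert G.n == 4
        assert len(G.edges()) == 8
        assert G.label("1", "2").atoms == ("k1", "x")
        assert G.label("3", "4").atoms == ("k7", "x")

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loops forbidden"):
            build_graph([(1, 1, "a")])

    def test_parallel_edge_rejected(self):
        with pytest.raises(ValueError, match="parallel edge"):
            build_graph([(1, 2, "a"), (1, 2, "b")])

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError, match="bad label expression"):
            build_graph([(1, 2, "k1**x")])

    def test_vertices_in_first_appearance_order(self):
        G = build_graph([(3, 1, "a"), (1, 2, "b")])
        assert G.vertices == ["3", "1", "2"]


class TestLaplacian:
    def test_two_vertex(self, two_state):
        L = laplacian(two_state, {"a": 1, "b": 1})
        assert np.allclose(L, [[-1, 1], [1, -1]])

    def test_column_sums_zero(self, fig2, make_assignment):
        L = laplacian(fig2, make_assignment(fig2))
        assert np.max(np.abs(L.sum(axis=0))) <= 1e-12 * np.max(np.abs(L))

    def test_square_diagonal(self):
        G = fixture("fig1_square")
        assignment = {s: 1.0 for s in G.atoms()}
        L = laplacian(G, assignment)
        assert L[0, 0] == pytest.approx(-2.0)
        assert np.allclose(L.sum(axis=0), 0)

    def test_missing_parameter(self, two_state):
        with pytest.raises(KeyError, match="unassigned symbol"):
            laplacian(two_state, {"a": 1})

    def test_nonpositive_value(self, two_state):
        with pytest.raises(ValueError, match="positive"):
            laplacian(two_state, {"a": 1, "b": 0})


class TestSCC:
    def test_absorbing_example_partial_order(self, fig3):
        scc = scc_decomposition(fig3)
        assert scc.components == (("1", "2", "3"), ("4",), ("5",))
        assert scc.order == frozenset({(0, 1), (1, 2), (0, 2)})
        assert scc.terminal == (("5",),)

    def test_strongly_connected_single_component(self, fig2):
        scc = scc_decomposition(fig2)
        assert len(scc.components) == 1
        assert scc.terminal == scc.components

    def test_two_terminal_components(self, fig4):
        scc = scc_decomposition(fig4)
        assert set(scc.terminal) == {("5",), ("6",)}

    def test_terminal_always_exists(self, fork):
        assert len(scc_decomposition(fork).terminal) >= 1

    def test_strong_connectivity_iff_one_component(self, two_state, fork, fig2):
        for G in (two_state, fig2):
            assert is_strongly_connected(G)
            assert len(scc_decomposition(G).components) == 1
        assert not is_strongly_connected(fork)
        one_way = build_graph([(1, 2, "a")])
        assert not is_strongly_connected(one_way)


class TestRemoveOutgoingEdges:
    def test_reproduces_absorbing_example(self, fig2, fig3):
        H = remove_outgoing_edges(fig2, {"5"})
        assert sorted((s, t) for s, t, _ in H.edges()) == sorted(
            (s, t) for s, t, _ in fig3.edges()
        )

    def test_idempotent(self, fig2):
        H1 = remove_outgoing_edges(fig2, {"5"})
        H2 = remove_outgoing_edges(H1, {"5"})
        assert sorted(H1.edges(), key=str) == sorted(H2.edges(), key=str)

    def test_noop_without_outgoing(self, fork):
        H = remove_outgoing_edges(fork, {"2"})
        assert len(H.edges()) == len(fork.edges())

    def test_two_vertex(self, two_state):
        H = remove_outgoing_edges(two_state, {"2"})
        assert [(s, t) for s, t, _ in H.edges()] == [("1", "2")]
        assert H.vertices == ["1", "2"]

    def test_unknown_vertex(self, two_state):
        with pytest.raises(KeyError, match="no such vertex"):
            remove_outgoing_edges(two_state, {"9"})


class TestCycleCondition:
    def test_square_at_equilibrium(self):
        G = fixture("fig1_square")
        # single independent cycle 1-2-4-3-1: condition is k1*k5*k8*k4 = k2*k6*k7*k3
        assignment = {s: 1.0 for s in G.atoms()}
        result = check_cycle_condition(G, assignment)
        assert result.reversible and result.satisfied
        assert result.worst_cycle_ratio == pytest.approx(1.0)

    def test_square_off_equilibrium(self):
        G = fixture("fig1_square")
        assignment = {s: 1.0 for s in G.atoms()}
        assignment["k1"] = 2.0
        result = check_cycle_condition(G, assignment)
        assert result.reversible and not result.satisfied
        assert not math.isclose(result.worst_cycle_ratio, 1.0)

    def test_pipeline_irreversible(self):
        G = build_pipeline(fixture("fig5a_pipeline"))
        result = check_cycle_condition(G, {s: 1.0 for s in G.atoms()})
        assert not result.reversible and not result.satisfied

    def test_reversible_tree_trivially_satisfied(self):
        G = build_graph([(1, 2, "a"), (2, 1, "b"), (2, 3, "c"), (3, 2, "d")])
        result = check_cycle_condition(G, {"a": 1, "b": 5, "c": 2, "d": 7})
        assert result.reversible and result.satisfied
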