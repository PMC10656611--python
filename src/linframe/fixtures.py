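"""Worked-example graphs and seeded random strongly connected graphs.

The example graphs cover the canonical teaching cases of the calculus: the
two-ligand binding square, a five-vertex strongly connected graph and its
absorbing variant, a six-vertex splitting-probability graph with two
terminal vertices, and single-/multi-block enzyme pipelines.  The larger
example graphs were transcribed from drawn figures, so their adjacency is
validated at build time against independently known rooted-forest counts
(20 spanning trees at vertex 5 and a unique tree at vertex 3 for the
five-vertex graph; 24 doubly-rooted forests for its absorbing variant; 18
forests rooted at {5, 6}, 6 of them with a path 1~>5, for the six-vertex
graph).  A transcription that fails these counts raises at build time —
it is never silently patched.
"""

from __future__ import annotations

import numpy as np

from .forests import enumerate_rooted_forests, enumerate_rooted_forests_with_path
from .graph import LabeledDigraph, build_graph, remove_outgoing_edges
from .pipeline import PipelineSpec

__all__ = ["fixture", "FIXTURE_NAMES", "random_graph"]

_FIG2_RECORDS = [
    (1, 2, "k1"),
    (1, 4, "k2"),
    (1, 5, "k3"),
    (2, 1, "k4"),
    (2, 3, "k5"),
    (2, 4, "k6"),
    (3, 1, "k7"),
    (3, 2, "k8"),
    (3, 4, "k9"),
    (4, 5, "k10"),
    (5, 1, "k11"),
]

_FIG4_RECORDS = [
    (1, 2, "k1"),
    (1, 4, "k2"),
    (2, 1, "k3"),
    (2, 3, "k4"),
    (3, 2, "k5"),
    (3, 4, "k6"),
    (3, 6, "k7"),
    (4, 1, "k8"),
    (4, 3, "k9"),
    (4, 5, "k10"),
    (4, 6, "k11"),
]

_FIG1_RECORDS = [
    (1, 2, "k1*x"),
    (2, 1, "k2"),
    (1, 3, "k3*y"),
    (3, 1, "k4"),
    (2, 4, "k5*y"),
    (4, 2, "k6"),
    (3, 4, "k7*x"),
    (4, 3, "k8"),
]

_validated = False


def _validate_transcriptions() -> None:
    """Check the drawn-figure transcriptions against their printed counts."""
    global _validated
    if _validated:
        return
    fig2 = build_graph(_FIG2_RECORDS)
    counts = {
        "trees rooted at 5": (len(enumerate_rooted_forests(fig2, {"5"})), 20),
        "trees rooted at 3": (len(enumerate_rooted_forests(fig2, {"3"})), 1),
    }
    fig3 = remove_outgoing_edges(fig2, {"5"})
    n24 = sum(
        len(enumerate_rooted_forests_with_path(fig3, {j, "5"}, "1", j))
        for j in ["1", "2", "3", "4"]
    )
    counts["doubly-rooted forests with path from 1"] = (n24, 24)
    fig4 = build_graph(_FIG4_RECORDS)
    counts["forests rooted at {5,6}"] = (
        len(enumerate_rooted_forests(fig4, {"5", "6"})),
        18,
    )
    counts["forests with path 1~>5"] = (
        len(enumerate_rooted_forests_with_path(fig4, {"5", "6"}, "1", "5")),
        6,
    )
    bad = {k: v for k, v in counts.items() if v[0] != v[1]}
    if bad:
        raise AssertionError(f"fixture transcription failed count validation: {bad}")
    _validated = True


FIXTURE_NAMES = (
    "fig1_square",
    "fig2_strong",
    "fig3_absorbing",
    "fig4_twotarget",
    "fig5a_pipeline",
    "fig5c_blocks",
    "two_state",
    "cycle3",
    "fork",
    "erlang_chain",
)


def fixture(name: str) -> LabeledDigraph | PipelineSpec:
    """A named example graph or pipeline spec (a fresh copy each call)."""
    if name in ("fig2_strong", "fig3_absorbing", "fig4_twotarget"):
        _validate_transcriptions()
    if name == "fig1_square":
        return build_graph(_FIG1_RECORDS)
    if name == "fig2_strong":
        return build_graph(_FIG2_RECORDS)
    if name == "fig3_absorbing":
        return remove_outgoing_edges(build_graph(_FIG2_RECORDS), {"5"})
    if name == "fig4_twotarget":
        return build_graph(_FIG4_RECORDS)
    if name == "fig5a_pipeline":
        return PipelineSpec.create(8, binding_sites=[2, 4])
    if name == "fig5c_blocks":
        return PipelineSpec.create(8, binding_sites=[1, 4, 6], irreversible=[3, 5])
    if name == "two_state":
        return build_graph([(1, 2, "a"), (2, 1, "b")])
    if name == "cycle3":
        return build_graph([(1, 2, "a"), (2, 3, "b"), (3, 1, "c")])
    if name == "fork":
        return build_graph([(1, 2, "a"), (1, 3, "b")])
    if name == "erlang_chain":
        return build_graph([(1, 2, "r"), (2, 3, "r"), (3, 4, "r")])
    raise KeyError(f"unknown fixture: {name!r}")


def random_graph(n_vertices: int, extra_edges: int, seed: int) -> LabeledDigraph:
    """Seeded strongly connected random graph with fresh symbolic labels.

    A Hamiltonian cycle over the vertices guarantees strong connectivity;
    ``extra_edges`` additional ordered pairs are sampled uniformly without
    duplicating existing edges.  Labels are e1, e2, ... in insertion order.
    """
    if n_vertices < 2:
        raise ValueError("need at least 2 vertices")
    capacity = n_vertices * (n_vertices - 1) - n_vertices
    if extra_edges > capacity:
        raise ValueError(
            f"extra_edges={extra_edges} exceeds the {capacity} pairs left beyond the cycle"
        )
    rng = np.random.default_rng(seed)
    records: list[tuple[object, object, str]] = []
    counter = 0
    present: set[tuple[int, int]] = set()
    for i in range(1, n_vertices + 1):
        j = i % n_vertices + 1
        counter += 1
        records.append((i, j, f"e{counter}"))
        present.add((i, j))
    added = 0
    while added < extra_edges:
        i = int(rng.integers(1, n_vertices + 1))
        j = int(rng.integers(1, n_vertices + 1))
        if i == j or (i, j) in present:
            continue
        counter += 1
        records.append((i, j, f"e{counter}"))
        present.add((i, j))
        added += 1
    return build_graph(records)
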