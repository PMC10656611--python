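"""Matrix-Tree steady states.

For a strongly connected graph the Laplacian kernel is one-dimensional and
is spanned by the vector of spanning-tree weights rho_i(G) = sum of w(F)
over the trees rooted at i.  Normalising gives the stationary probability
of each vertex as a manifestly positive rational function of the labels.
"""

from __future__ import annotations

from .algebra import PositivePolynomial, RationalFunction
from .forests import enumerate_rooted_forests, forest_sum
from .graph import LabeledDigraph, is_strongly_connected

__all__ = ["rho", "steady_state"]


def rho(G: LabeledDigraph, i: str) -> PositivePolynomial:
    """Unnormalised steady-state weight of vertex i: the rooted-tree sum.

    Zero polynomial if no spanning tree is rooted at i (possible only for
    graphs that are not strongly connected).
    """
    G.require_vertex(i)
    return forest_sum(enumerate_rooted_forests(G, {i}))


def steady_state(G: LabeledDigraph) -> list[RationalFunction]:
    """Normalised stationary distribution, component i = rho_i / sum_j rho_j.

    The common denominator is kept uncancelled; under any positive
    assignment the components are positive and sum to 1.
    """
    if not is_strongly_connected(G):
        raise ValueError("steady state requires strong connectivity")
    weights = [rho(G, v) for v in G.vertices]
    total = PositivePolynomial.zero()
    for w in weights:
        total = total + w
    return [RationalFunction(w, total) for w in weights]
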