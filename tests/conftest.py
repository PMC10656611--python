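import numpy as np
import pytest

from linframe import build_graph, fixture, prepare_targets


@pytest.fixture
def two_state():
    return fixture("two_state")


@pytest.fixture
def fork():
    return fixture("fork")


@pytest.fixture
def fig2():
    return fixture("fig2_strong")


@pytest.fixture
def fig3():
    return fixture("fig3_absorbing")


@pytest.fixture
def fig4():
    return fixture("fig4_twotarget")


@pytest.fixture
def chain_ab():
    """1 -> 2 -> 3 with rates a then b."""
    return build_graph([(1, 2, "a"), (2, 3, "b")])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_assignment(atoms, rng, low=0.2, high=3.0):
    return {a: float(rng.uniform(low, high)) for a in sorted(atoms)}


@pytest.fixture
def make_assignment(rng):
    return lambda G: random_assignment(G.atoms(), rng)
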