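import numpy as np
import pytest

import netgame as ng


@pytest.fixture
def pd_game():
    """Canonical prisoner's dilemma at maximal temptation."""
    return ng.get_game("pd_canonical")


@pytest.fixture
def k5():
    return ng.make_graph("complete", n=5)


@pytest.fixture
def star5():
    """Star with 5 leaves; hub is n1."""
    return ng.make_graph("star", leaves=5)


@pytest.fixture
def fast_spec():
    """Short convergence spec for cheap stochastic tests."""
    return ng.ConvergenceSpec(window=10, max_rounds=500, min_replicates=5,
                              max_replicates=200, batch_size=5)


def random_networks(count, max_n, seed, p=0.35):
    """Reproducible batch of Erdős–Rényi test graphs (n >= 3)."""
    rng = np.random.default_rng(seed)
    nets = []
    for _ in range(count):
        n = int(rng.integers(3, max_n + 1))
        nets.append(ng.make_graph("erdos_renyi", n=n, p=p,
                                  seed=int(rng.integers(2**31 - 1))))
    return nets
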