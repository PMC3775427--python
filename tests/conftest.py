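import numpy as np
import pytest

import netshift as ns


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_modular_spec():
    """Four planted 15-node modules at study-like weight levels."""
    return ns.ModularSpec(n_nodes=60, module_sizes=[15] * 4, mu_in=0.6,
                          mu_out=0.2, sigma=0.1, seed=7)


@pytest.fixture
def small_pair(small_modular_spec):
    """A task/rest pair with a planted hub and between-module boosts (n=60)."""
    return ns.make_task_rest_pair(spec=small_modular_spec, seed=7,
                                  hub_node=3, hub_boost=0.5)


def random_symmetric(n, rng, labels=None):
    """Random weighted ConnectivityMatrix with distinct weights."""
    w = rng.random((n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 1.0)
    return ns.ConnectivityMatrix(w, labels or [f"n{i}" for i in range(n)])


def random_graph(n, p, rng):
    """Erdős–Rényi G(n, p) BinaryGraph."""
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < p
    return ns.BinaryGraph(n, iu[keep].astype(np.int64) * n + ju[keep])
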