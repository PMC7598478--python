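import numpy as np
import pytest

from redsim.network import ContactNetwork, generate_configuration_network


@pytest.fixture
def small_config_net():
    """Fixed 50-node truncated power-law network (beta=2.5, k_min=3)."""
    return generate_configuration_network(50, 2.5, 3, seed=7)


@pytest.fixture
def tiny_net():
    """30-node configuration network for cheap equivalence ensembles."""
    return generate_configuration_network(30, 2.5, 3, seed=3)


@pytest.fixture
def star10():
    """Star K_{1,9}: hub 0, leaves 1..9."""
    return ContactNetwork(10, [(0, i) for i in range(1, 10)])


@pytest.fixture
def pair_net():
    return ContactNetwork(2, [(0, 1)])


def run_ensemble(engine_fn, factory, n_replicas, seed0, horizon, statistic):
    """One scalar per replica; replica i uses the single stream seed0+i."""
    out = []
    for i in range(n_replicas):
        rng = np.random.default_rng(seed0 + i)
        model = factory(rng)
        traj = engine_fn(model, horizon, rng)
        out.append(statistic(traj))
    return np.asarray(out)


@pytest.fixture
def ensemble():
    return run_ensemble
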