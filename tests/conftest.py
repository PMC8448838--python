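import numpy as np
import pytest

import tmesim as ts
from tmesim import vasculature as vasc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def desk_config():
    return ts.desk_preset()


@pytest.fixture
def tiny_config():
    """A 5x5 lattice for fast mechanics tests."""
    return ts.SimulationConfig(domain_cm=0.1, initial_cells=10, n_episodes=10,
                               n_repetitions=1)


@pytest.fixture
def tiny_grid(tiny_config):
    return ts.build_grid(tiny_config)


@pytest.fixture
def phantom_pair(rng):
    """A seeded synthetic angiogram plus its ground-truth graph."""
    params = vasc.PhantomParams()
    return vasc.synth_phantom(params, np.random.default_rng(7))
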