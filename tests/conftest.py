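import numpy as np
import pytest

from lpfdti.simulation import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Desk-scale study conditions: same physics, 20^3 grid for speed."""
    return SimulationConfig(grid_shape=(20, 20, 20))


@pytest.fixture
def tiny_config():
    return SimulationConfig(grid_shape=(14, 14, 14))


def random_symmetric(rng, scale=0.05):
    a = rng.normal(scale=scale, size=(3, 3))
    return 0.5 * (a + a.T)


def random_spd_tensor(rng, scale=1e-3):
    a = rng.normal(size=(3, 3))
    return scale * (a @ a.T + 0.5 * np.eye(3))
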