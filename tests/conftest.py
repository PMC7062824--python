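import numpy as np
import pytest

from popcast.synthetic import SyntheticWorldConfig, make_world


@pytest.fixture(scope="session")
def config():
    return SyntheticWorldConfig(seed=7)


@pytest.fixture(scope="session")
def world(config):
    return make_world(config)


@pytest.fixture(scope="session")
def small_world():
    """Three provinces on a small raster: fast fixture for engine tests."""
    return make_world(SyntheticWorldConfig(
        n_provinces=3, raster_shape=(48, 48), coarse_factor=8, seed=11,
    ))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
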