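import numpy as np
import pytest

from amyseg.phantom import PhantomParams, make_base_phantom, simulate_cohort
from amyseg.volumes import Volume


@pytest.fixture(scope="session")
def small_params():
    """32^3 phantom parameters used by most registration-level tests."""
    return PhantomParams(shape=(32, 32, 32), warp_amplitude=2.0, warp_smoothness=4.0)


@pytest.fixture(scope="session")
def default_params():
    return PhantomParams()


@pytest.fixture(scope="session")
def base_small(small_params):
    return make_base_phantom(small_params)


@pytest.fixture(scope="session")
def base_default(default_params):
    return make_base_phantom(default_params)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    """4 train + 2 test subjects at 32^3 (shared across expensive tests)."""
    return simulate_cohort(4, 2, small_params, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def blob_volume():
    """Interior-supported smooth blob on a 16^3 unit grid."""
    x = np.arange(16)
    xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
    data = np.exp(-(((xx - 8) ** 2 + (yy - 8) ** 2 + (zz - 8) ** 2) / 2.0))
    data[data < 1e-12] = 0.0
    return Volume(data)
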