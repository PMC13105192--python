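import numpy as np
import pytest

from connspectra.scenes import make_scene, sample_cross_spectra
from connspectra.spectral import default_grid


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def small_scene():
    """Coupled 12-vertex scene shared by fast unit tests."""
    return make_scene(12, 8, density=0.3, alpha_fraction=0.3,
                      xi_fraction=0.3, seed=5)


@pytest.fixture(scope="session")
def small_ensemble(small_scene):
    return sample_cross_spectra(small_scene, m=100, seed=6)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
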