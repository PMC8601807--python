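import numpy as np
import pytest
from hypothesis import settings as _hsettings

_hsettings.register_profile("deterministic", derandomize=True)
_hsettings.load_profile("deterministic")

from oslalm.geometry import Image, make_geometry
from oslalm.phantoms import PhantomSpec, make_phantom
from oslalm.simulate import NoiseModel, simulate_sinogram


@pytest.fixture(scope="session")
def tiny_geom():
    """8x8 image, 12 views, 13 bins — dense-oracle scale."""
    return make_geometry(8, 8, 1.0, 12, 13, 1.0)


@pytest.fixture(scope="session")
def small_geom():
    """16x16 image, 12 views, 23 bins — adjointness-test scale."""
    return make_geometry(16, 16, 1.0, 12, 23, 1.0)


@pytest.fixture(scope="session")
def default_geom():
    """The benchmark acquisition geometry."""
    return make_geometry(128, 128, 1.0, 120, 185, 1.0)


@pytest.fixture(scope="session")
def shepp_logan_128():
    return make_phantom(PhantomSpec(kind="shepp_logan", n=128))


@pytest.fixture(scope="session")
def default_noisy_data(default_geom, shepp_logan_128):
    """Seeded noisy sinogram + weights on the benchmark instance."""
    return simulate_sinogram(shepp_logan_128, default_geom, NoiseModel(1e5, seed=0))


@pytest.fixture(scope="session")
def tiny_noisy_data(tiny_geom):
    rng = np.random.default_rng(3)
    truth = Image(rng.random((8, 8)) * 0.04, 1.0)
    ybar, w = simulate_sinogram(truth, tiny_geom, NoiseModel(1e5, seed=1))
    return truth, ybar, w
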