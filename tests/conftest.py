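import numpy as np
import pytest

from miefield.incident import OpticalConfig
from miefield.materials import MaterialSpectrum
from miefield.scatter import Scene, Sphere, aperture_samples


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def surface_directions(rng):
    """64 unit vectors, fixed across the suite."""
    v = rng.normal(size=(64, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


@pytest.fixture
def na062_config():
    """Schwarzschild-style condenser: inner NA 0.34, outer NA 0.62."""
    return OpticalConfig.from_na(2.5, 0.34, 0.62)


@pytest.fixture
def lens_config():
    return OpticalConfig.from_na(2.5, 0.0, 0.62)


def make_scene(spheres, config, m=200, seed=7):
    sampling = aperture_samples(config.alpha1, config.alpha2, m, seed)
    return Scene(spheres, config, sampling)


@pytest.fixture
def single_sphere_scene(lens_config):
    mat = MaterialSpectrum.constant(1.4 + 0.02j)
    return make_scene([Sphere([0.0, 0.0, 0.0], 1.0, mat)], lens_config)
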