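import numpy as np
import pytest

from hsinuclei.cube_io import HyperCube
from hsinuclei.simulate import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cube(rng):
    """Random 8x8x5 raw cube with an arbitrary increasing band grid."""
    data = rng.random((8, 8, 5)) * 1000
    return HyperCube(data, wavelengths=[500, 550, 600, 650, 700])


def make_two_region_cube(n=24, seed=0, contrast=1.0):
    """Left half one spectrum, right half another, plus noise.

    Returns (cube, ground_truth_mask) with the right half True.
    """
    rng = np.random.default_rng(seed)
    lam = np.linspace(470, 720, 6)
    s1 = np.array([0.9, 0.8, 0.6, 0.5, 0.6, 0.7])
    s2 = np.array([0.5, 0.4, 0.7, 0.8, 0.7, 0.5])
    data = np.empty((n, n, 6))
    half = n // 2
    data[:, :half] = s1 + (1 - contrast) * (s2 - s1) / 2
    data[:, half:] = s2 - (1 - contrast) * (s2 - s1) / 2
    data += rng.normal(0, 0.01, data.shape)
    truth = np.zeros((n, n), dtype=bool)
    truth[:, half:] = True
    return HyperCube(np.clip(data, 0, 1.5), lam, "transmittance"), truth


@pytest.fixture(scope="session")
def nuclei_scene():
    """A mid-size rendered scene shared by segmentation-level tests."""
    spec = SceneSpec(shape=(320, 320), n_nuclei=40, label="cancerous", seed=7)
    return generate_scene(spec)
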