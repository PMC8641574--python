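import numpy as np
import pytest

from leafcs import HyperCube, SceneParams, generate_leaf_scene


@pytest.fixture(scope="session")
def leaf_scene():
    """Default synthetic scene: 64x64x32, three leaves, mild noise."""
    params = SceneParams(rng_seed=1)
    cube, labels = generate_leaf_scene(params)
    return cube, labels, params


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_cube(rng, rows=4, cols=5, bands=3, bit_depth=16):
    full = (1 << bit_depth) - 1
    data = rng.integers(0, full + 1, size=(rows, cols, bands), dtype=np.uint16)
    wl = np.linspace(450.0, 950.0, bands)
    return HyperCube(data=data, wavelengths=wl, bit_depth=bit_depth)
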