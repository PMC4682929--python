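import numpy as np
import pytest

from pettex import SUV, VOIMask, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20250927)


@pytest.fixture
def row_volume():
    """1x1x3 SUV row whose RR levels at D=2 are [1, 2, 3]."""
    values = np.array([[[2.0, 3.0, 4.0]]])
    return VolumeGrid(values, (4.0, 4.0, 4.0), unit=SUV)


def random_lattice(rng, shape=(4, 4, 4), n_levels=5, p_mask=0.7):
    """Random gray-level lattice plus a non-empty random mask."""
    levels = rng.integers(1, n_levels + 1, size=shape)
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask[tuple(rng.integers(0, s) for s in shape)] = True
    return levels, mask


@pytest.fixture
def suv_cube(rng):
    """8x8x8 positive SUV volume with a random blob mask of >= 20 voxels."""
    values = rng.gamma(4.0, 1.0, size=(8, 8, 8))
    vol = VolumeGrid(values, (4.0, 4.0, 4.0), unit=SUV)
    mask = np.zeros((8, 8, 8), dtype=bool)
    mask[2:6, 2:6, 2:6] = rng.random((4, 4, 4)) < 0.8
    mask[3, 3, 3] = True
    return vol, VOIMask(mask)
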