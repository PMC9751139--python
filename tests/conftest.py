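import numpy as np
import pytest

from stimmap.data_model import EFieldImage, VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """5x5x5 grid, 2 mm isotropic, centred on the origin."""
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = -4.0
    return VoxelGrid(affine, np.zeros((5, 5, 5)))


@pytest.fixture
def random_field(rng, small_grid):
    return EFieldImage(small_grid.like(rng.random((5, 5, 5))), "p0")


def make_field(grid, values, pid=""):
    return EFieldImage(grid.like(np.asarray(values, dtype=float)), pid)
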