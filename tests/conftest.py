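import numpy as np
import pytest

from lateralink.core_io import BoldRun, Mask, StatMap, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid():
    """Small centered 3 mm grid with even dims (no voxel on the midline)."""
    return VolumeGrid.isotropic((8, 10, 8), 3.0)


@pytest.fixture
def brain_mask(grid):
    return Mask(grid, np.ones(grid.n_voxels, bool), "brain")


def make_run(grid, data, tr=3.0, subject_id="sub-01"):
    return BoldRun(grid, data, tr, subject_id)


@pytest.fixture
def noise_run(grid, rng):
    return make_run(grid, rng.standard_normal((40, grid.n_voxels)))


def statmap(grid, values, kind="t", df=40.0):
    return StatMap(grid, values, kind, df if kind == "t" else 0.0)
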