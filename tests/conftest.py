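import numpy as np
import pytest

from wmatlas.streamline_core import BinaryMask, VolumeGrid
from wmatlas.synthetic_cohort import CohortSpec, make_template


@pytest.fixture(scope="session")
def unit_grid():
    """8^3 grid with 1 mm voxels, world == voxel coordinates."""
    return VolumeGrid(shape=(8, 8, 8), affine=np.eye(4))


@pytest.fixture(scope="session")
def default_template():
    """The default 12-tract synthetic template (built once per session)."""
    return make_template(CohortSpec(seed=0))


def mask_from_voxels(grid, voxels):
    vals = np.zeros(grid.shape, dtype=bool)
    for v in voxels:
        vals[tuple(v)] = True
    return BinaryMask(grid=grid, values=vals)


@pytest.fixture(scope="session")
def make_mask():
    return mask_from_voxels
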