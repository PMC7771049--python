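import numpy as np
import pytest

from veinscape import BinaryMask, Volume3D, VoxelGrid


@pytest.fixture
def unit_grid():
    """Small unit-spacing grid centred on the origin."""
    return VoxelGrid(shape=(9, 9, 9), spacing=(1.0, 1.0, 1.0),
                     origin=(-4.0, -4.0, -4.0))


@pytest.fixture
def shell_mask(unit_grid):
    """Spherical shell between radii 2.5 and 4 on the 9^3 grid."""
    centers = unit_grid.all_voxel_centers()
    r = np.linalg.norm(centers, axis=1).reshape(unit_grid.shape)
    return BinaryMask(unit_grid, (r >= 2.5) & (r <= 4.0))


@pytest.fixture
def ramp_volume(unit_grid):
    """Volume whose value is the flat voxel index, handy for thresholds."""
    vals = np.arange(np.prod(unit_grid.shape), dtype=float).reshape(unit_grid.shape)
    return Volume3D(unit_grid, vals, modality="angiographic")


def acceptance_shell_mask():
    """Cortex-shell mask on the full-size 128^3, 1.5 mm phantom grid."""
    from veinscape.phantom import make_shell_mask

    grid = VoxelGrid(
        shape=(128, 128, 128), spacing=(1.5, 1.5, 1.5),
        origin=tuple(-(128 - 1) / 2 * 1.5 for _ in range(3)),
    )
    return make_shell_mask(grid)
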