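import numpy as np
import pytest

from vsdprint.core import BinaryVascularVolume, VoxelGrid
from vsdprint.synth import TubeSpec, rasterize_mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cylinder(
    n: int = 40,
    voxel_size: float = 1.0,
    radius_vox: float = 4.0,
    direction=(1.0, 0.0, 0.0),
    center=None,
) -> tuple[BinaryVascularVolume, TubeSpec]:
    """Digitized cylinder spanning the grid along an arbitrary direction."""
    grid = VoxelGrid((n, n, n), voxel_size)
    extent = np.array(grid.extent_um)
    c = extent / 2.0 if center is None else np.asarray(center, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    half = 2.0 * extent.max()  # long enough to span the box in any direction
    tube = TubeSpec(tuple(c - half * d), tuple(c + half * d), radius_vox * voxel_size)
    mask = rasterize_mask([tube], grid)
    return BinaryVascularVolume(mask, grid), tube


def make_ball(n: int = 24, voxel_size: float = 1.0, radius_vox: float = 5.0):
    grid = VoxelGrid((n, n, n), voxel_size)
    c = (n - 1) / 2.0
    ax = np.arange(n, dtype=float)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    mask = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius_vox**2
    return BinaryVascularVolume(mask, grid), np.array([c, c, c])
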