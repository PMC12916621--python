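import numpy as np
import pytest

from perifc.volumes_io import BinaryMask, Volume4D, VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def scanner_grid():
    """A small grid with the scanner's voxel geometry and TR."""
    return VoxelGrid(dims=(8, 8, 6), voxel_mm=(3.75, 3.75, 4.0), tr_s=2.4)


def small_subject_volume(rng, dims=(8, 8, 8), n_frames=60, tr_s=2.4):
    """A random 4D volume with an ellipsoidal brain and a tiny lateral cavity.

    Returns (series4d, brain_mask, resection_mask); everything outside the
    brain is zero, cavity voxels are exactly zero.
    """
    grid = VoxelGrid(dims=dims, voxel_mm=(3.75, 3.75, 4.0), tr_s=tr_s)
    centers = [(d - 1) / 2.0 for d in dims]
    ii, jj, kk = np.meshgrid(*(np.arange(d) for d in dims), indexing="ij")
    semi = [0.47 * d for d in dims]
    brain = (
        ((ii - centers[0]) / semi[0]) ** 2
        + ((jj - centers[1]) / semi[1]) ** 2
        + ((kk - centers[2]) / semi[2]) ** 2
    ) <= 1.0
    cx = max(1, dims[0] // 4)
    resection = np.zeros(dims, dtype=bool)
    resection[cx, dims[1] // 2, dims[2] // 2] = True
    resection &= brain
    series = rng.normal(size=dims + (n_frames,))
    series[~brain] = 0.0
    series[resection] = 0.0
    return (
        Volume4D(grid, series),
        BinaryMask(grid, brain),
        BinaryMask(grid, resection),
    )
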