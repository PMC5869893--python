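import numpy as np
import pytest
from hypothesis import settings as hyp_settings

from lexiplan.grid import VoxelGrid

hyp_settings.register_profile("ci", derandomize=True, deadline=None)
hyp_settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def iso1_grid():
    """Small 1 mm isotropic grid for exact distance-transform oracles."""
    return VoxelGrid(dims=(21, 21, 21), spacing=(1.0, 1.0, 1.0),
                     origin=(-10.0, -10.0, -10.0))


@pytest.fixture
def ball(iso1_grid):
    """Radius-6 mm ball centred in iso1_grid."""
    x, y, z = iso1_grid.coordinate_arrays()
    return x**2 + y**2 + z**2 <= 6.0**2


def brute_force_distance(mask, grid):
    """Exhaustive per-voxel Euclidean distance (mm) to the nearest voxel
    centre of ``mask``; the independent oracle for all distance-based
    geometry operators.  O(n^2), keep grids <= ~40^3."""
    pts = grid.points(np.arange(grid.n_voxels))
    src = grid.points(np.flatnonzero(mask))
    out = np.empty(grid.n_voxels)
    chunk = 2048
    for i in range(0, pts.shape[0], chunk):
        d2 = ((pts[i:i + chunk, None, :] - src[None, :, :]) ** 2).sum(axis=2)
        out[i:i + chunk] = np.sqrt(d2.min(axis=1))
    return out.reshape(grid.shape)
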