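import numpy as np
import pytest

from orthofusion.grid import BoneMask, VoxelGrid, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(20240403)


@pytest.fixture
def random_volume(rng):
    """8x8x8 random intensity volume on a unit grid."""
    return Volume(VoxelGrid((8, 8, 8), (1.0, 1.0, 1.0)), rng.normal(500, 150, (8, 8, 8)))


def make_ball_mask(radius_mm: float, spacing: float = 0.5, pad_mm: float = 4.0) -> BoneMask:
    """Binary ball of the given radius centred at the world origin."""
    n = int(2 * (radius_mm + pad_mm) / spacing) + 1
    grid = VoxelGrid((n, n, n), (spacing,) * 3, origin=(-(n - 1) / 2 * spacing,) * 3)
    centers = grid.voxel_centers()
    values = (np.linalg.norm(centers, axis=-1) <= radius_mm).astype(np.uint8)
    return BoneMask(grid, values)


def brute_force_trilinear(values: np.ndarray, idx: np.ndarray) -> float:
    """Independent 8-corner trilinear oracle: w = prod(1 - |delta|)."""
    base = np.floor(idx).astype(int)
    base = np.minimum(base, np.array(values.shape) - 2)
    base = np.maximum(base, 0)
    total = 0.0
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                corner = base + np.array([di, dj, dk])
                w = np.prod(1.0 - np.abs(idx - corner))
                total += w * values[tuple(corner)]
    return total
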