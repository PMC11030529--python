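"""Voxel-grid geometry, volumes and trilinear resampling.

The whole pipeline speaks one currency: a :class:`Volume`, i.e. a 3-D
intensity lattice plus the geometry that places it in world space.  World
coordinates are millimetres in a right-handed frame.  The ``origin`` of a
grid is the world position of the *center* of voxel ``(0, 0, 0)`` and the
sampleable domain is the voxel-center hull — the convex span of voxel
centers, i.e. continuous indices in ``[0, shape - 1]`` per axis.  This
matches how medical-image headers (NIfTI, MetaImage) describe geometry and
makes identity resampling exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "Volume",
    "BoneMask",
    "OutsideFieldOfViewError",
    "trilinear_sample",
    "sample_points",
    "resample",
]

# continuous-index slack when testing hull membership; absorbs float noise
# from the world<->index round trip without admitting real extrapolation
_HULL_TOL = 1e-7
# continuous indices this close to an integer snap to it, so sampling at a
# voxel center returns the stored value bit-for-bit
_SNAP_TOL = 1e-9


class OutsideFieldOfViewError(ValueError):
    """A sample point lies outside the voxel-center hull of a volume."""


def _as_direction(direction) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    if d.shape != (3, 3):
        raise ValueError(f"direction must be a 3x3 matrix, got shape {d.shape}")
    if not np.allclose(d.T @ d, np.eye(3), atol=1e-9):
        raise ValueError("direction matrix columns must be orthonormal (tol 1e-9)")
    return d


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry-only description of a 3-D sampling lattice.

    Parameters
    ----------
    shape
        Number of voxels per axis ``(nx, ny, nz)``; each entry >= 1.
    spacing
        Voxel spacing in mm per axis; strictly positive.
    origin
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    direction
        3x3 orthonormal matrix whose *columns* are the world directions of
        the grid axes.  Identity means grid axes == world axes.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("shape, spacing and origin must have 3 entries")
        if any(n < 1 for n in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        d = _as_direction(self.direction)
        d.flags.writeable = False
        object.__setattr__(self, "direction", d)

    # -- geometry ---------------------------------------------------------
    def index_to_world(self, index) -> np.ndarray:
        """Map continuous indices (..., 3) to world mm coordinates."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + (idx * np.asarray(self.spacing)) @ self.direction.T

    def world_to_index(self, point) -> np.ndarray:
        """Map world mm coordinates (..., 3) to continuous indices."""
        pt = np.asarray(point, dtype=float)
        return ((pt - np.asarray(self.origin)) @ self.direction) / np.asarray(self.spacing)

    def contains_index(self, index, tol: float = _HULL_TOL) -> np.ndarray:
        """True where a continuous index lies inside the voxel-center hull."""
        idx = np.asarray(index, dtype=float)
        hi = np.asarray(self.shape, dtype=float) - 1.0
        return np.all((idx >= -tol) & (idx <= hi + tol), axis=-1)

    def contains_point(self, point, tol: float = _HULL_TOL) -> np.ndarray:
        return self.contains_index(self.world_to_index(point), tol=tol)

    def hull_corners(self) -> np.ndarray:
        """World coordinates of the 8 corners of the voxel-center hull."""
        hi = np.asarray(self.shape, dtype=float) - 1.0
        corners = np.array(
            [[i * hi[0], j * hi[1], k * hi[2]] for i in (0, 1) for j in (0, 1) for k in (0, 1)]
        )
        return self.index_to_world(corners)

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(*shape, 3)``."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n, dtype=float) for n in self.shape], indexing="ij"),
            axis=-1,
        )
        return self.index_to_world(idx)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


@dataclass
class Volume:
    """A 3-D real-valued intensity lattice on a :class:`VoxelGrid`.

    Intensities are carried as floating point regardless of the on-disk
    type: fusion averages and the similarity metrics all need real
    arithmetic.
    """

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must all be finite")

    def copy(self) -> "Volume":
        return Volume(self.grid, self.values.copy())


@dataclass
class BoneMask:
    """Binary lattice (0 background, 1 bone) on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.values = v.astype(np.uint8)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())


# -- sampling -------------------------------------------------------------

def _snap_indices(idx: np.ndarray) -> np.ndarray:
    rounded = np.round(idx)
    return np.where(np.abs(idx - rounded) <= _SNAP_TOL, rounded, idx)


def sample_points(volume: Volume, points) -> tuple[np.ndarray, np.ndarray]:
    """Trilinearly sample ``volume`` at world points (..., 3).

    Returns ``(values, inside)``: interpolated intensities and a boolean
    lattice flagging which points lay inside the voxel-center hull.  Points
    outside the hull get the nearest-edge value; callers decide the policy
    via the flag (fusion uses it to count true coverage per voxel).
    """
    pts = np.asarray(points, dtype=float)
    idx = _snap_indices(volume.grid.world_to_index(pts))
    inside = volume.grid.contains_index(idx)
    flat = idx.reshape(-1, 3)
    vals = ndimage.map_coordinates(
        volume.values, flat.T, order=1, mode="nearest"
    )
    return vals.reshape(idx.shape[:-1]), inside


def trilinear_sample(volume: Volume, point) -> float:
    """Sample one world point; raise if it is outside the field of view."""
    value, inside = sample_points(volume, np.asarray(point, dtype=float))
    if not bool(inside):
        raise OutsideFieldOfViewError(
            f"point {tuple(np.asarray(point, float))} is outside the voxel-center hull"
        )
    return float(value)


def resample(volume: Volume, target: VoxelGrid) -> tuple[Volume, np.ndarray]:
    """Resample ``volume`` onto ``target`` by trilinear interpolation.

    Every target voxel center is mapped to world space and sampled from the
    source.  Returns the resampled volume and a boolean validity mask that
    is False where the target center fell outside the source hull (those
    voxels hold the clamped nearest-edge value).
    """
    if target.n_voxels == 0:
        raise ValueError("degenerate target grid (zero voxels)")
    if target.same_geometry(volume.grid):
        return volume.copy(), np.ones(target.shape, dtype=bool)
    # source_index = A @ target_index + b; letting affine_transform generate
    # the coordinates keeps memory flat on large grids
    sp_t = np.asarray(target.spacing)
    sp_s = np.asarray(volume.grid.spacing)
    A = (volume.grid.direction.T @ target.direction) * sp_t[None, :] / sp_s[:, None]
    b = volume.grid.world_to_index(np.asarray(target.origin))
    vals = ndimage.affine_transform(
        volume.values, A, offset=b, output_shape=target.shape,
        order=1, mode="nearest", prefilter=False,
    )
    inside = _inside_mask(volume.grid, target, A, b)
    return Volume(target, vals), inside


def _inside_mask(source: VoxelGrid, target: VoxelGrid, A: np.ndarray, b: np.ndarray) -> np.ndarray:
    hi = np.asarray(source.shape, dtype=float) - 1.0
    if np.allclose(A, np.diag(np.diag(A)), atol=1e-12):
        # axis-aligned case: hull membership separates per axis
        per_axis = []
        for k in range(3):
            c = _snap_indices_1d(A[k, k] * np.arange(target.shape[k]) + b[k])
            per_axis.append((c >= -_HULL_TOL) & (c <= hi[k] + _HULL_TOL))
        return (
            per_axis[0][:, None, None]
            & per_axis[1][None, :, None]
            & per_axis[2][None, None, :]
        )
    idx = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in target.shape], indexing="ij"),
        axis=-1,
    )
    return source.contains_index(_snap_indices(idx @ A.T + b))


def _snap_indices_1d(x: np.ndarray) -> np.ndarray:
    rounded = np.round(x)
    return np.where(np.abs(x - rounded) <= _SNAP_TOL, rounded, x)
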