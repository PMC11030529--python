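"""Vertebra-like digital phantoms for exercising the fusion pipeline.

A phantom is a set of ellipsoidal "vertebral bodies", each with a bright
cortical shell and a dimmer trabecular core, embedded in a soft-tissue
background.  Two adjacent bodies separated by a sub-millimetre gap emulate
a facet joint: the gap is comparable to a clinical slice thickness, so it
is exactly the structure that anisotropic clinical volumes blur away and
that orthogonal fusion should recover.

Voxel intensities are Hounsfield-unit-like.  Partial volume is modelled by
subvoxel supersampling of the analytic shape (``supersample**3`` points per
voxel) before additive Gaussian noise; ``supersample=1`` gives a pure
three-level phantom.  Generation is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grid import BoneMask, VoxelGrid, Volume

__all__ = ["PhantomSpec", "make_phantom", "mask_to_dilated_eval_mask", "two_body_spec"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of an ellipsoid-body phantom.

    ``gap`` is the minimum separation (mm) between adjacent body surfaces;
    generation fails if any pair of bodies is closer.  Intensities are
    ``(background, trabecular, cortical)`` HU and must be increasing.
    """

    body_centers: tuple[tuple[float, float, float], ...]
    body_radii: tuple[tuple[float, float, float], ...]
    cortical_thickness: float = 1.5
    gap: float = 1.2
    intensities: tuple[float, float, float] = (0.0, 300.0, 1200.0)
    noise_sigma: float = 25.0
    seed: int = 0
    grid: VoxelGrid = field(
        default_factory=lambda: VoxelGrid((128, 128, 128), (0.6, 0.6, 0.6))
    )
    supersample: int = 3

    def __post_init__(self):
        if len(self.body_centers) != len(self.body_radii):
            raise ValueError("need one radii triple per body center")
        if self.cortical_thickness <= 0:
            raise ValueError("cortical_thickness must be > 0")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        bg, trab, cort = self.intensities
        if not (cort > trab > bg):
            raise ValueError("intensities must satisfy cortical > trabecular > background")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")


def two_body_spec(
    grid: VoxelGrid | None = None,
    gap: float = 1.2,
    noise_sigma: float = 25.0,
    seed: int = 0,
    supersample: int = 3,
) -> PhantomSpec:
    """Default two-body phantom: coaxial ellipsoids stacked along z.

    Centers are placed so the analytic surface-to-surface separation along
    z equals ``gap`` exactly, with the pair centred in the grid extent.
    """
    if grid is None:
        grid = VoxelGrid((128, 128, 128), (0.6, 0.6, 0.6))
    extent = [(n - 1) * s for n, s in zip(grid.shape, grid.spacing)]
    cx, cy, cz = (e / 2 for e in extent)
    rz = 11.0
    half_sep = rz + gap / 2.0
    centers = ((cx, cy, cz - half_sep), (cx, cy, cz + half_sep))
    radii = ((16.0, 14.0, rz), (16.0, 14.0, rz))
    return PhantomSpec(
        body_centers=centers,
        body_radii=radii,
        gap=gap,
        noise_sigma=noise_sigma,
        seed=seed,
        grid=grid,
        supersample=supersample,
    )


def _coaxial_gap(spec: PhantomSpec, i: int, j: int) -> float:
    """Surface separation between two bodies along the line of centers.

    Exact for coaxial aligned ellipsoids; for general placements it is the
    support-width bound along the center line (conservative).
    """
    ci = np.asarray(spec.body_centers[i], float)
    cj = np.asarray(spec.body_centers[j], float)
    d = cj - ci
    dist = np.linalg.norm(d)
    if dist == 0:
        return -np.inf
    u = d / dist
    ri = np.linalg.norm(np.asarray(spec.body_radii[i]) * u)
    rj = np.linalg.norm(np.asarray(spec.body_radii[j]) * u)
    return dist - ri - rj


def _validate_layout(spec: PhantomSpec) -> None:
    grid = spec.grid
    lo = np.asarray(grid.index_to_world((0.0, 0.0, 0.0)))
    hi = np.asarray(grid.index_to_world(tuple(n - 1.0 for n in grid.shape)))
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    for c, r in zip(spec.body_centers, spec.body_radii):
        c, r = np.asarray(c, float), np.asarray(r, float)
        if np.any(c - r < lo) or np.any(c + r > hi):
            raise ValueError(f"body at {tuple(c)} exceeds the grid extent")
    n = len(spec.body_centers)
    for i in range(n):
        for j in range(i + 1, n):
            g = _coaxial_gap(spec, i, j)
            if g < spec.gap - 1e-9:
                raise ValueError(
                    f"bodies {i} and {j} are separated by {g:.3f} mm < gap {spec.gap} mm"
                )


def _ellipsoid_norm(points: np.ndarray, center, radii) -> np.ndarray:
    """||(p - c) / r||; <= 1 inside the ellipsoid."""
    scaled = (points - np.asarray(center, float)) / np.asarray(radii, float)
    return np.sqrt(np.sum(scaled * scaled, axis=-1))


def _ellipsoid_norm2_separable(
    grid: VoxelGrid, offset: tuple[float, float, float], center, radii
) -> np.ndarray:
    """||(p - c) / r||^2 on an axis-aligned grid via per-axis broadcasting."""
    c = np.asarray(center, float)
    r = np.asarray(radii, float)
    terms = []
    for k in range(3):
        pos = grid.origin[k] + (np.arange(grid.shape[k]) + offset[k]) * grid.spacing[k]
        terms.append(((pos - c[k]) / r[k]) ** 2)
    return (
        terms[0][:, None, None] + terms[1][None, :, None] + terms[2][None, None, :]
    )


def make_phantom(spec: PhantomSpec) -> tuple[Volume, list[BoneMask], PhantomSpec]:
    """Generate the phantom volume, one mask per body, and the analytic spec.

    Each subvoxel point is classified against every body: trabecular inside
    the inner ellipsoid (semi-axes shrunk by ``cortical_thickness``),
    cortical in the shell between inner and outer ellipsoid, background
    elsewhere.  Voxel HU is the supersample mean; the per-body mask marks
    voxels whose inside fraction is >= 0.5.  The returned spec (with its
    centers/radii) is the analytic ground-truth surface description.
    """
    _validate_layout(spec)
    grid = spec.grid
    bg, trab, cort = spec.intensities
    ss = spec.supersample
    # subvoxel offsets in index units, centred on the voxel center
    offs = (np.arange(ss) - (ss - 1) / 2.0) / ss
    hu = np.zeros(grid.shape, dtype=float)
    inside_frac = [np.zeros(grid.shape, dtype=float) for _ in spec.body_centers]
    separable = np.allclose(grid.direction, np.eye(3), atol=1e-12)
    base_idx = None
    if not separable:
        base_idx = np.stack(
            np.meshgrid(*[np.arange(n, dtype=float) for n in grid.shape], indexing="ij"),
            axis=-1,
        )
    inner_radii = [
        np.maximum(np.asarray(r, float) - spec.cortical_thickness, 1e-6)
        for r in spec.body_radii
    ]
    for ox in offs:
        for oy in offs:
            for oz in offs:
                sub = np.full(grid.shape, bg, dtype=float)
                for b, (c, r) in enumerate(zip(spec.body_centers, spec.body_radii)):
                    if separable:
                        outer = _ellipsoid_norm2_separable(grid, (ox, oy, oz), c, r) <= 1.0
                        inner = (
                            _ellipsoid_norm2_separable(grid, (ox, oy, oz), c, inner_radii[b])
                            <= 1.0
                        )
                    else:
                        pts = grid.index_to_world(base_idx + np.array([ox, oy, oz]))
                        outer = _ellipsoid_norm(pts, c, r) <= 1.0
                        inner = _ellipsoid_norm(pts, c, inner_radii[b]) <= 1.0
                    sub[outer & ~inner] = cort
                    sub[inner] = trab
                    inside_frac[b] += outer
                hu += sub
    hu /= ss**3
    masks = [
        BoneMask(grid, (f / ss**3 >= 0.5).astype(np.uint8)) for f in inside_frac
    ]
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sigma, size=grid.shape)
    return Volume(grid, hu), masks, replace(spec)


def mask_to_dilated_eval_mask(mask: BoneMask, margin_mm: float) -> BoneMask:
    """Dilate a mask by a Euclidean ball of radius ``margin_mm`` (world mm).

    Implemented with the exact Euclidean distance transform of the
    background (anisotropic sampling honoured), so a voxel joins the mask
    iff its center is within ``margin_mm`` of a foreground voxel center.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    if margin_mm == 0 or mask.values.all():
        return BoneMask(mask.grid, mask.values.copy())
    dist = ndimage.distance_transform_edt(
        mask.values == 0, sampling=mask.grid.spacing
    )
    return BoneMask(mask.grid, (dist <= margin_mm + 1e-9).astype(np.uint8))
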