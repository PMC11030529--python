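"""Simulate clinical anisotropic CT from a high-resolution volume.

A clinical acquisition with thick slices is emulated in two steps along the
chosen through-plane axis: convolve with a Gaussian slice-sensitivity
profile (FWHM defaulting to the slice thickness), then sample slice centers
spaced ``target_thickness`` apart, the first coinciding with the first
source slice center.  The in-plane axes are untouched.

The "resliced" comparison case interpolates a clinical volume back to fine
through-plane spacing with a Lanczos kernel ``sinc(x) * sinc(x / a)`` for
``|x| < a`` (x in source-slice index units), weights renormalized to unit
sum so constants are preserved near the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VoxelGrid, Volume

__all__ = [
    "DegradeSpec",
    "simulate_clinical",
    "reslice_lanczos",
    "make_orthogonal_clinical_set",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class DegradeSpec:
    """Degradation parameters.

    ``blur_fwhm`` is the FWHM (mm) of the Gaussian slice profile; None
    means "equal to target_thickness".  ``lanczos_a`` is the kernel support
    in source-slice units.
    """

    through_axis: int = 2
    target_thickness: float = 3.0
    blur_fwhm: float | None = None
    lanczos_a: int = 3
    reslice_spacing: float = 0.6

    def __post_init__(self):
        if self.through_axis not in (0, 1, 2):
            raise ValueError("through_axis must be 0, 1 or 2")
        if self.target_thickness <= 0 or self.reslice_spacing <= 0:
            raise ValueError("thickness and reslice spacing must be > 0")
        if self.lanczos_a < 1:
            raise ValueError("lanczos_a must be >= 1")

    @property
    def fwhm(self) -> float:
        return self.target_thickness if self.blur_fwhm is None else self.blur_fwhm


def _axis_grid(grid: VoxelGrid, axis: int, new_spacing: float, n_new: int) -> VoxelGrid:
    spacing = list(grid.spacing)
    shape = list(grid.shape)
    spacing[axis] = new_spacing
    shape[axis] = n_new
    return VoxelGrid(tuple(shape), tuple(spacing), grid.origin, grid.direction)


def _slice_centers(span: float, step: float) -> np.ndarray:
    # first output center at the first source center; last inside the hull
    n = int(np.floor(span / step + 1e-9)) + 1
    return np.arange(n) * step


def _apply_axis_weights(values: np.ndarray, weights: np.ndarray, axis: int) -> np.ndarray:
    """Contract ``values`` along ``axis`` with an (n_out, n_src) weight matrix."""
    moved = np.moveaxis(values, axis, -1)
    out = moved @ weights.T
    return np.moveaxis(out, -1, axis)


def simulate_clinical(hr: Volume, spec: DegradeSpec) -> Volume:
    """Blur-and-decimate ``hr`` along the through-plane axis.

    Output slice ``i`` is the Gaussian-weighted average of source slices,
    with weights ``exp(-d^2 / 2 sigma^2)`` (d = center distance in mm)
    normalized to unit sum; ``blur_fwhm == 0`` degenerates to linear
    sampling at the new slice centers.
    """
    axis = spec.through_axis
    src_sp = hr.grid.spacing[axis]
    if spec.target_thickness < src_sp - 1e-12:
        raise ValueError(
            f"target thickness {spec.target_thickness} mm must not be finer than the "
            f"source through-plane spacing {src_sp} mm"
        )
    n_src = hr.grid.shape[axis]
    src_pos = np.arange(n_src) * src_sp
    out_pos = _slice_centers(src_pos[-1], spec.target_thickness)
    sigma = spec.fwhm * FWHM_TO_SIGMA
    if sigma > 0:
        d = out_pos[:, None] - src_pos[None, :]
        w = np.exp(-0.5 * (d / sigma) ** 2)
    else:
        w = _linear_weights(out_pos / src_sp, n_src)
    w /= w.sum(axis=1, keepdims=True)
    values = _apply_axis_weights(hr.values, w, axis)
    return Volume(_axis_grid(hr.grid, axis, spec.target_thickness, len(out_pos)), values)


def _linear_weights(x: np.ndarray, n_src: int) -> np.ndarray:
    rounded = np.round(x)
    x = np.where(np.abs(x - rounded) <= 1e-9, rounded, x)
    w = np.zeros((len(x), n_src))
    lo = np.clip(np.floor(x).astype(int), 0, n_src - 1)
    hi = np.clip(lo + 1, 0, n_src - 1)
    frac = x - lo
    for i, (l, h, f) in enumerate(zip(lo, hi, frac)):
        w[i, l] += 1 - f
        w[i, h] += f
    return w


def lanczos_kernel(x: np.ndarray, a: int) -> np.ndarray:
    """Windowed-sinc kernel sinc(x)*sinc(x/a) on |x| < a, zero outside."""
    x = np.asarray(x, dtype=float)
    out = np.sinc(x) * np.sinc(x / a)
    return np.where(np.abs(x) < a, out, 0.0)


def reslice_lanczos(clin: Volume, spec: DegradeSpec) -> Volume:
    """Interpolate ``clin`` back to fine through-plane spacing (Lanczos)."""
    axis = spec.through_axis
    src_sp = clin.grid.spacing[axis]
    if spec.reslice_spacing > src_sp + 1e-12:
        raise ValueError(
            f"reslice spacing {spec.reslice_spacing} mm must not be coarser than the "
            f"source through-plane spacing {src_sp} mm"
        )
    n_src = clin.grid.shape[axis]
    out_pos = _slice_centers((n_src - 1) * src_sp, spec.reslice_spacing)
    x = out_pos[:, None] / src_sp - np.arange(n_src)[None, :]
    w = lanczos_kernel(x, spec.lanczos_a)
    w /= w.sum(axis=1, keepdims=True)
    values = _apply_axis_weights(clin.values, w, axis)
    return Volume(_axis_grid(clin.grid, axis, spec.reslice_spacing, len(out_pos)), values)


def make_orthogonal_clinical_set(hr: Volume, spec: DegradeSpec) -> list[Volume]:
    """Simulate the axial/coronal/sagittal clinical triplet from one HR volume.

    Applies :func:`simulate_clinical` once per grid axis, so each output is
    anisotropic along a different axis — the three orthogonal thick-slice
    reconstructions a clinical protocol would export.
    """
    from dataclasses import replace

    return [
        simulate_clinical(hr, replace(spec, through_axis=axis)) for axis in (0, 1, 2)
    ]
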