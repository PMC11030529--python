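"""Volume similarity metrics: local SSIM maps, masked statistics, PSNR, NCC.

The structural-similarity map compares two volumes voxel by voxel through
Gaussian-windowed local moments:

    SSIM(x) = (2 mu_a mu_b + C1)(2 cov_ab + C2)
              -----------------------------------
              (mu_a^2 + mu_b^2 + C1)(var_a + var_b + C2)

with C1 = (k1 L)^2, C2 = (k2 L)^2 and L the intensity dynamic range.  The
window is a separable 3-D Gaussian (side 11, sigma 1.5 voxels by default,
the reference SSIM parameters).  Masked statistics restrict the map to a
bone mask so the score reflects the anatomy of interest rather than empty
background; the mask is applied to the full-volume map, not to the inputs,
to avoid manufacturing artificial edges inside the windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import BoneMask, Volume

__all__ = ["SSIMParams", "SimilarityReport", "ssim_map", "masked_ssim_stats", "psnr", "ncc"]


@dataclass(frozen=True)
class SSIMParams:
    window: int = 11
    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float | None = None  # None: max - min of the reference

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be > 0")
        if self.dynamic_range is not None and self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be > 0")

    def gaussian_window(self) -> np.ndarray:
        """Normalized 1-D Gaussian tap weights of length ``window``."""
        half = self.window // 2
        x = np.arange(-half, half + 1, dtype=float)
        w = np.exp(-0.5 * (x / self.sigma) ** 2)
        return w / w.sum()


@dataclass
class SimilarityReport:
    """Image-similarity summary for one case against the reference."""

    case: str
    ssim_mean_masked: float
    ssim_std_masked: float
    ssim_mean_whole: float
    ssim_std_whole: float
    psnr_db: float

    def to_dict(self) -> dict:
        return {
            "case": self.case,
            "ssim_mean_masked": self.ssim_mean_masked,
            "ssim_std_masked": self.ssim_std_masked,
            "ssim_mean_whole": self.ssim_mean_whole,
            "ssim_std_whole": self.ssim_std_whole,
            "psnr_db": self.psnr_db,
        }


def _require_same_grid(a: Volume, b) -> None:
    if not a.grid.same_geometry(b.grid):
        raise ValueError(
            "volumes are on different grids; resample one onto the other first"
        )


def _local_mean(values: np.ndarray, w: np.ndarray) -> np.ndarray:
    out = values
    for axis in range(values.ndim):
        out = ndimage.correlate1d(out, w, axis=axis, mode="reflect")
    return out


def ssim_map(a: Volume, b: Volume, params: SSIMParams = SSIMParams()) -> Volume:
    """Per-voxel local SSIM of two volumes on the same grid (values in [-1, 1])."""
    _require_same_grid(a, b)
    L = params.dynamic_range
    if L is None:
        L = float(b.values.max() - b.values.min())
        if L <= 0:
            L = 1.0
    c1 = (params.k1 * L) ** 2
    c2 = (params.k2 * L) ** 2
    w = params.gaussian_window()
    av, bv = a.values, b.values
    mu_a = _local_mean(av, w)
    mu_b = _local_mean(bv, w)
    var_a = _local_mean(av * av, w) - mu_a * mu_a
    var_b = _local_mean(bv * bv, w) - mu_b * mu_b
    cov = _local_mean(av * bv, w) - mu_a * mu_b
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    return Volume(a.grid, num / den)


def masked_ssim_stats(ssim: Volume, mask: BoneMask | None = None) -> tuple[float, float]:
    """Mean and sample std (ddof=1) of the SSIM map under a mask.

    ``mask=None`` uses the whole volume.  A single-voxel mask has no sample
    variance; its std is reported as 0.
    """
    if mask is None:
        vals = ssim.values.ravel()
    else:
        _require_same_grid(ssim, mask)
        if mask.n_foreground == 0:
            raise ValueError("mask is empty")
        vals = ssim.values[mask.values == 1]
    std = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), std


def psnr(a: Volume, b: Volume, dynamic_range: float) -> float:
    """Peak signal-to-noise ratio 10*log10(L^2 / MSE) in dB; inf when a == b."""
    _require_same_grid(a, b)
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be > 0")
    mse = float(np.mean((a.values - b.values) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(dynamic_range**2 / mse)


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Global zero-mean normalized cross-correlation of two images, in [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    da = a - a.mean()
    db = b - b.mean()
    na = np.linalg.norm(da)
    nb = np.linalg.norm(db)
    if na == 0 or nb == 0:
        raise ValueError("NCC is undefined for a zero-variance image")
    return float(np.clip(np.dot(da.ravel(), db.ravel()) / (na * nb), -1.0, 1.0))
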