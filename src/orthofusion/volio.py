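"""Read/write volumes in NIfTI (.nii/.nii.gz) and MetaImage (.mha/.mhd).

SimpleITK does the header work; this module only translates between its
image model and :class:`~orthofusion.grid.Volume`.  SimpleITK indexes
images ``(x, y, z)`` but returns arrays ``(z, y, x)``, so arrays are
transposed both ways; geometry (spacing, origin, direction) transfers
verbatim — the direction matrix columns are the world directions of the
grid axes in both models.
"""

from __future__ import annotations

import os

import numpy as np
import SimpleITK as sitk

from .grid import BoneMask, VoxelGrid, Volume

__all__ = ["read_volume", "write_volume", "read_mask", "SUPPORTED_EXTENSIONS"]

SUPPORTED_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_extension(path: str) -> None:
    p = str(path).lower()
    if not p.endswith(SUPPORTED_EXTENSIONS):
        raise ValueError(
            f"unsupported volume format for {path!r}; expected one of {SUPPORTED_EXTENSIONS}"
        )


def read_volume(path) -> Volume:
    """Read a volume; geometry comes from the native header fields.

    Raises a ``ValueError`` naming the file for unsupported extensions,
    unreadable headers, or a non-orthogonal direction matrix.
    """
    _check_extension(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # malformed header etc.
        raise ValueError(f"could not read volume {path!r}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(f"{path!r}: expected a 3-D volume, got {img.GetDimension()}-D")
    direction = np.array(img.GetDirection(), dtype=float).reshape(3, 3)
    try:
        grid = VoxelGrid(
            shape=img.GetSize(),
            spacing=img.GetSpacing(),
            origin=img.GetOrigin(),
            direction=direction,
        )
    except ValueError as exc:
        raise ValueError(f"{path!r}: invalid geometry: {exc}") from exc
    values = sitk.GetArrayFromImage(img).astype(float).transpose(2, 1, 0)
    return Volume(grid, values)


def write_volume(volume: Volume, path, dtype=np.float32) -> None:
    """Write a volume; default on-disk dtype float32.

    Integer dtypes quantize by rounding; the in-memory pipeline always
    works in float.
    """
    _check_extension(path)
    values = volume.values
    if np.issubdtype(np.dtype(dtype), np.integer):
        values = np.round(values)
    arr = np.ascontiguousarray(values.transpose(2, 1, 0).astype(dtype))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in volume.grid.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.grid.origin))
    img.SetDirection(tuple(volume.grid.direction.ravel()))
    sitk.WriteImage(img, str(path))


def read_mask(path) -> BoneMask:
    """Read a binary bone mask (any value > 0.5 counts as bone)."""
    vol = read_volume(path)
    return BoneMask(vol.grid, (vol.values > 0.5).astype(np.uint8))
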