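"""In-memory containers for CT volumes and masks, plus NIfTI round-tripping.

Arrays are indexed ``(slice, row, col)`` — i.e. (z, y, x) — 0-based, and
``spacing_mm`` follows the same (z, y, x) order.  NIfTI files store data in
(x, y, z) order with spacing in the header zooms; the readers/writers here
transpose so that in-memory arrays always follow the package convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["CTVolume", "GTVMask", "NormalizedVolume",
           "save_nifti", "read_nifti", "HU_MIN", "HU_MAX"]

HU_MIN, HU_MAX = -1024.0, 3071.0


@dataclass
class CTVolume:
    """A raw CT grid in Hounsfield units with its geometry metadata."""

    voxels: np.ndarray                      # (slices, rows, cols), HU
    spacing_mm: tuple[float, float, float]  # (z, y, x)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxel grid must be a non-empty 3-D array")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        lo, hi = self.voxels.min(), self.voxels.max()
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(
                f"HU range [{lo:.1f}, {hi:.1f}] outside calibrated "
                f"[{HU_MIN}, {HU_MAX}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class GTVMask:
    """Binary gross-tumor-volume delineation aligned to a CT grid."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        vals = np.unique(self.voxels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask must be strictly binary, found values {vals[:5]}")
        self.voxels = self.voxels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def volume_mm3(self) -> float:
        return float(self.voxels.sum()) * float(np.prod(self.spacing_mm))


@dataclass
class NormalizedVolume:
    """Windowed, [0, 1]-normalized intensity grid ready for the network."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.min() < 0.0 or self.voxels.max() > 1.0:
            raise ValueError("normalized intensities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def save_nifti(path: str | Path, voxels: np.ndarray,
               spacing_mm: tuple[float, float, float]) -> None:
    """Write a (z, y, x) array to NIfTI with (z, y, x) spacing in the header."""
    sz, sy, sx = spacing_mm
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(np.asarray(voxels).T, affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI file back into (z, y, x) array order; inverse of save_nifti."""
    img = nib.load(str(path))
    voxels = np.asanyarray(img.dataobj).T
    sx, sy, sz = img.header.get_zooms()[:3]
    return voxels, (float(sz), float(sy), float(sx))
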