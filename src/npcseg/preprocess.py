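"""Ingestion, resampling, HU windowing and the five-scale crop datasets.

The pipeline mirrors routine head-CT preparation for segmentation networks:

1. read a DICOM series or NIfTI file into a ``CTVolume``;
2. resample to a uniform (z, y, x) spacing of (3.0, 1.0, 1.0) mm — slice
   thickness is acquisition-fixed at 3 mm, in-plane spacing varies per
   patient;
3. window Hounsfield units to [-150, 500] and map linearly to [0, 1];
   values outside the window are set to exactly 0 (so both air and dense
   bone are blanked — a deliberate, literal reading of the protocol this
   reproduces, which makes -150 HU and out-of-window values coincide);
4. crop at one of five named scales (extra-small ... extra-large) whose
   fractions shrink from the full grid in fixed decrements: 15% per step
   in-plane starting at 100%, 10% per step in z starting at 90%;
5. optionally augment with random flips, in-plane right-angle rotations,
   transposition and sub-cropping, applied identically to image and label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pydicom
from scipy import ndimage

from .volume import CTVolume, GTVMask, NormalizedVolume, HU_MIN, HU_MAX, read_nifti

__all__ = [
    "TARGET_SPACING", "HU_WINDOW", "ScaleSpec", "CropSample",
    "load_volume", "resample_to_spacing", "window_and_normalize",
    "canonical_scales", "crop_multiscale", "augment",
]

log = logging.getLogger(__name__)

TARGET_SPACING = (3.0, 1.0, 1.0)   # (z, y, x) mm
HU_WINDOW = (-150.0, 500.0)

SCALE_NAMES = ("extra-small", "small", "medium", "large", "extra-large")
_XY_FRACTIONS = (0.40, 0.55, 0.70, 0.85, 1.00)   # 15% decrements from 100%
_Z_FRACTIONS = (0.50, 0.60, 0.70, 0.80, 0.90)    # 10% decrements from 90%


@dataclass(frozen=True)
class ScaleSpec:
    """One of the five canonical crop scales."""

    name: str
    xy_fraction: float
    z_fraction: float

    def __post_init__(self) -> None:
        if not (0 < self.xy_fraction <= 1 and 0 < self.z_fraction <= 1):
            raise ValueError(f"fractions must lie in (0, 1], got {self}")


@dataclass
class CropSample:
    """A cropped training example; ``label`` is None for unlabeled data."""

    image: np.ndarray
    label: np.ndarray | None
    scale: ScaleSpec
    patient_id: str = ""
    offset: tuple[int, int, int] = (0, 0, 0)


def canonical_scales() -> list[ScaleSpec]:
    """The five crop scales, ordered extra-small -> extra-large."""
    return [ScaleSpec(n, xy, z)
            for n, xy, z in zip(SCALE_NAMES, _XY_FRACTIONS, _Z_FRACTIONS)]


# ---- ingestion -----------------------------------------------------------

def _load_dicom_series(directory: Path) -> CTVolume:
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm"
                   or p.is_file() and not p.name.startswith("."))
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:  # non-DICOM clutter in the directory
            continue
    if not datasets:
        raise ValueError(f"no readable DICOM slices in {directory}")
    datasets.sort(key=lambda d: float(getattr(d, "ImagePositionPatient",
                                              [0, 0, d.InstanceNumber])[2]))
    first = datasets[0]
    shape2d = (int(first.Rows), int(first.Columns))
    orientation = getattr(first, "ImageOrientationPatient", None)
    slices = []
    for d in datasets:
        if (int(d.Rows), int(d.Columns)) != shape2d:
            raise ValueError("DICOM series has slices with mismatched dimensions")
        if orientation is not None and \
                list(getattr(d, "ImageOrientationPatient", orientation)) != list(orientation):
            raise ValueError("DICOM series mixes image orientations")
        slope = float(getattr(d, "RescaleSlope", 1.0))
        intercept = float(getattr(d, "RescaleIntercept", 0.0))
        slices.append(d.pixel_array.astype(np.float64) * slope + intercept)
    voxels = np.clip(np.stack(slices), HU_MIN, HU_MAX)
    ps = [float(v) for v in getattr(first, "PixelSpacing", [1.0, 1.0])]
    if len(datasets) > 1:
        z0 = float(datasets[0].ImagePositionPatient[2])
        z1 = float(datasets[1].ImagePositionPatient[2])
        dz = abs(z1 - z0) or float(getattr(first, "SliceThickness", 1.0))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    pid = str(getattr(first, "PatientID", directory.name))
    return CTVolume(voxels, (dz, ps[0], ps[1]), patient_id=pid)


def load_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    ``format`` may be "nifti" or "dicom-series"; by default it is inferred
    (directory -> DICOM series, file -> NIfTI).  HU values are clipped to
    the calibrated [-1024, 3071] range on ingestion.
    """
    path = Path(path)
    if format is None:
        format = "dicom-series" if path.is_dir() else "nifti"
    if format == "dicom-series":
        return _load_dicom_series(path)
    if format == "nifti":
        voxels, spacing = read_nifti(path)
        voxels = np.clip(voxels.astype(np.float64), HU_MIN, HU_MAX)
        return CTVolume(voxels, spacing, patient_id=path.stem.split(".")[0])
    raise ValueError(f"unknown format {format!r}")


# ---- resampling and normalization ---------------------------------------

def resample_to_spacing(vol: CTVolume, mask: GTVMask | None = None,
                        target: tuple[float, float, float] = TARGET_SPACING,
                        ) -> tuple[CTVolume, GTVMask | None]:
    """Resample to uniform spacing; trilinear for the image, nearest for the
    mask (so it stays strictly binary).  Output shape per axis is
    round(input_shape * input_spacing / target_spacing)."""
    zoom = tuple(s / t for s, t in zip(vol.spacing_mm, target))
    if zoom == (1.0, 1.0, 1.0):
        out_vol = CTVolume(vol.voxels.copy(), target, vol.origin_mm, vol.patient_id)
        out_mask = GTVMask(mask.voxels.copy(), target) if mask is not None else None
        return out_vol, out_mask
    voxels = ndimage.zoom(vol.voxels, zoom, order=1, mode="nearest")
    voxels = np.clip(voxels, HU_MIN, HU_MAX)
    out_vol = CTVolume(voxels, target, vol.origin_mm, vol.patient_id)
    out_mask = None
    if mask is not None:
        m = ndimage.zoom(mask.voxels, zoom, order=0, mode="nearest")
        if m.shape != voxels.shape:
            raise ValueError("mask and volume resampled to different shapes")
        out_mask = GTVMask(m, target)
    return out_vol, out_mask


def window_and_normalize(vol: CTVolume, low: float = HU_WINDOW[0],
                         high: float = HU_WINDOW[1]) -> NormalizedVolume:
    """Map HU in [low, high] linearly to [0, 1]; everything outside to 0."""
    if low >= high:
        raise ValueError(f"window low {low} must be below high {high}")
    v = vol.voxels
    out = (v - low) / (high - low)
    out[(v < low) | (v > high)] = 0.0
    return NormalizedVolume(out, vol.spacing_mm, vol.patient_id)


# ---- multi-scale cropping ------------------------------------------------

def _containing_offset(rng: np.random.Generator, centroid: int, size: int,
                       dim: int) -> int:
    """Uniform offset whose half-open window [off, off+size) holds centroid."""
    lo = max(0, centroid - size + 1)
    hi = min(centroid, dim - size)
    if hi < lo:  # centroid too close to an edge for any full window: clip
        lo = hi = int(np.clip(centroid - size // 2, 0, dim - size))
    return int(rng.integers(lo, hi + 1))


def crop_multiscale(vol: NormalizedVolume, mask: GTVMask, scale: ScaleSpec,
                    rng: np.random.Generator) -> CropSample:
    """Random crop at ``scale`` whose window contains the GTV centroid.

    Crop size per axis is floor(fraction * source size).  With an empty
    mask there is no centroid; placement falls back to uniform random (a
    warning is logged).
    """
    shape = vol.shape
    fracs = (scale.z_fraction, scale.xy_fraction, scale.xy_fraction)
    sizes = tuple(max(1, int(np.floor(f * s))) for f, s in zip(fracs, shape))
    if mask.voxels.any():
        centroid = tuple(int(round(c)) for c in
                         ndimage.center_of_mass(mask.voxels))
        offset = tuple(_containing_offset(rng, c, sz, d)
                       for c, sz, d in zip(centroid, sizes, shape))
    else:
        log.warning("empty GTV mask for %s: uniform random crop placement",
                    vol.patient_id or "<unnamed>")
        offset = tuple(int(rng.integers(0, d - sz + 1))
                       for sz, d in zip(sizes, shape))
    sl = tuple(slice(o, o + s) for o, s in zip(offset, sizes))
    return CropSample(vol.voxels[sl].copy(), mask.voxels[sl].copy(),
                      scale, vol.patient_id, offset)


# ---- augmentation --------------------------------------------------------

def augment(sample: CropSample, rng: np.random.Generator) -> CropSample:
    """Random flip / in-plane rotation / transpose / sub-crop, each applied
    independently with probability 0.5, identically to image and label.

    In-plane rotation and transposition are only applied when rows == cols
    (otherwise the sample shape would change); sub-cropping keeps 90% of
    each axis.  Labels stay strictly binary because every transform is a
    pure index operation.
    """
    img = sample.image
    lab = sample.label

    def both(fn):
        nonlocal img, lab
        img = fn(img)
        if lab is not None:
            lab = fn(lab)

    gates = rng.random(4)  # one gate per transform, drawn up front
    if gates[0] < 0.5:  # flip along a random axis
        ax = int(rng.integers(0, 3))
        both(lambda a: np.flip(a, axis=ax))
    square = img.shape[1] == img.shape[2]
    if gates[1] < 0.5 and square:  # in-plane right-angle rotation
        k = int(rng.integers(1, 4))
        both(lambda a: np.rot90(a, k, axes=(1, 2)))
    if gates[2] < 0.5 and square:  # in-plane transpose
        both(lambda a: np.swapaxes(a, 1, 2))
    if gates[3] < 0.5:  # random 90% sub-crop
        sizes = tuple(max(1, int(np.floor(0.9 * s))) for s in img.shape)
        off = tuple(int(rng.integers(0, d - s + 1))
                    for s, d in zip(sizes, img.shape))
        sl = tuple(slice(o, o + s) for o, s in zip(off, sizes))
        both(lambda a: a[sl])
    return replace(sample, image=np.ascontiguousarray(img),
                   label=None if lab is None else np.ascontiguousarray(lab))
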