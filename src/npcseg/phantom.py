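"""Seeded synthetic head-CT phantoms with optional gross-tumor-volume masks.

Clinical NPC planning CTs cannot be redistributed, so the rest of the
package is exercised on phantoms that reproduce the *format* of the real
cohort — 512x512xN HU grids with 3.0 mm slices and patient-varying in-plane
spacing, one irregular hyperintense tumor blob per labeled case, none for
the unlabeled "healthy" cases — without attempting anatomical realism.

Each phantom contains, in HU terms: air (~-1000) outside an elliptical head
outline, a cortical-bone skull ring (~700), smoothly varying soft tissue
(~40 +/- low-frequency texture), a small air cavity standing in for the
nasopharyngeal airway (~-800), and, when requested, an ellipsoidal tumor at
``tumor_hu`` whose surface is perturbed by low-frequency radial noise to
mimic irregular tumor morphology.  Everything is drawn from a single seeded
generator, so identical specs produce bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import CTVolume, GTVMask, HU_MIN, HU_MAX, save_nifti

__all__ = ["PhantomSpec", "LabeledCase", "UnlabeledCase",
           "generate_phantom", "generate_cases", "generate_cohort"]

# default cohort sizes mirror the study this emulates: 63 delineated NPC
# scans plus 50 healthy scans used only for pretraining
DEFAULT_N_LABELED = 63
DEFAULT_N_UNLABELED = 50


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; identical specs generate identical data.

    ``shape`` is (slices, rows, cols); the default 32x128x128 keeps
    desk-scale runtimes (full 512x512 grids are supported, just not the
    default).  ``tumor_center`` is a voxel coordinate (z, y, x); ``None``
    places the tumor at the grid center.  ``deformation`` scales the
    low-frequency radial perturbation of the tumor surface relative to its
    mean radius (0 gives an exact ellipsoid).
    """

    shape: tuple[int, int, int] = (32, 128, 128)
    spacing_mm: tuple[float, float, float] = (3.0, 1.0, 1.0)
    tumor_present: bool = True
    tumor_center: tuple[int, int, int] | None = None
    tumor_radii_mm: tuple[float, float, float] = (12.0, 12.0, 12.0)
    tumor_hu: float = 70.0
    noise_sd_hu: float = 15.0
    deformation: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ValueError(f"shape components must be >= 8, got {self.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if any(r < 0 for r in self.tumor_radii_mm):
            raise ValueError(f"tumor radii must be >= 0, got {self.tumor_radii_mm}")


@dataclass
class LabeledCase:
    patient_id: str
    volume: CTVolume
    mask: GTVMask

    def __post_init__(self) -> None:
        if self.mask.shape != self.volume.shape:
            raise ValueError("mask grid shape must equal volume grid shape")


@dataclass
class UnlabeledCase:
    patient_id: str
    volume: CTVolume


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int, int],
                  sigma: tuple[float, float, float]) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to unit standard deviation."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    sd = field.std()
    return field / sd if sd > 0 else field


def _tumor_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    nz, ny, nx = spec.shape
    cz, cy, cx = (spec.tumor_center if spec.tumor_center is not None
                  else (nz // 2, ny // 2, nx // 2))
    rz, ry, rx = (max(r, 1e-6) for r in spec.tumor_radii_mm)
    z, y, x = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                          indexing="ij", sparse=True)
    dist = np.sqrt(((z - cz) * spec.spacing_mm[0] / rz) ** 2
                   + ((y - cy) * spec.spacing_mm[1] / ry) ** 2
                   + ((x - cx) * spec.spacing_mm[2] / rx) ** 2)
    # low-frequency radial perturbation -> irregular but connected blob
    bump = _smooth_noise(rng, spec.shape, sigma=(2.0, 6.0, 6.0))
    mask = dist <= 1.0 + spec.deformation * bump
    if not mask.any():
        return mask.astype(np.uint8)
    labels, n = ndimage.label(mask)
    if n > 1:  # keep the component holding (or nearest) the nominal center
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask).astype(np.uint8)


def generate_phantom(spec: PhantomSpec) -> LabeledCase | UnlabeledCase:
    """Render one phantom; labeled (volume + mask) iff ``spec.tumor_present``."""
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij", sparse=True)
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r_head = np.sqrt(((yy - cy) / (0.42 * ny)) ** 2 + ((xx - cx) / (0.45 * nx)) ** 2)

    hu = np.full(spec.shape, -1000.0)
    tissue = r_head <= 1.0
    texture = _smooth_noise(rng, spec.shape, sigma=(1.0, 6.0, 6.0)) * 12.0
    hu[:, tissue] = 40.0 + texture[:, tissue]
    skull = (r_head > 0.86) & (r_head <= 1.0)
    hu[:, skull] = 700.0
    # nasopharyngeal-airway stand-in: small anterior air pocket
    az, ay, ax = nz // 2, int(cy - 0.25 * ny * 0.42), int(cx)
    z3, y3, x3 = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij", sparse=True)
    airway = (((z3 - az) * spec.spacing_mm[0] / 9.0) ** 2
              + ((y3 - ay) * spec.spacing_mm[1] / 6.0) ** 2
              + ((x3 - ax) * spec.spacing_mm[2] / 6.0) ** 2) <= 1.0
    hu[airway] = -800.0

    mask = np.zeros(spec.shape, dtype=np.uint8)
    if spec.tumor_present:
        mask = _tumor_mask(spec, rng)
        tumor_texture = _smooth_noise(rng, spec.shape, sigma=(1.0, 3.0, 3.0)) * 8.0
        hu[mask == 1] = spec.tumor_hu + tumor_texture[mask == 1]

    hu += rng.normal(0.0, spec.noise_sd_hu, size=spec.shape)
    np.clip(hu, HU_MIN, HU_MAX, out=hu)

    pid = f"phantom-{spec.seed:05d}"
    volume = CTVolume(hu, spec.spacing_mm, patient_id=pid)
    if not spec.tumor_present:
        return UnlabeledCase(pid, volume)
    return LabeledCase(pid, volume, GTVMask(mask, spec.spacing_mm))


def _cohort_specs(n_labeled: int, n_unlabeled: int, seed: int,
                  shape: tuple[int, int, int],
                  radii_range_mm: tuple[float, float]) -> list[PhantomSpec]:
    if n_labeled < 0 or n_unlabeled < 0:
        raise ValueError("case counts must be >= 0")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    specs = []
    for i in range(n_labeled + n_unlabeled):
        labeled = i < n_labeled
        inplane = float(rng.uniform(0.8, 1.2))  # slice thickness is fixed 3 mm
        center = (int(rng.integers(nz // 3, 2 * nz // 3 + 1)),
                  int(rng.integers(int(0.35 * ny), int(0.65 * ny))),
                  int(rng.integers(int(0.35 * nx), int(0.65 * nx))))
        radii = tuple(float(rng.uniform(*radii_range_mm)) for _ in range(3))
        specs.append(PhantomSpec(
            shape=shape,
            spacing_mm=(3.0, inplane, inplane),
            tumor_present=labeled,
            tumor_center=center if labeled else None,
            tumor_radii_mm=radii if labeled else (0.0, 0.0, 0.0),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        ))
    return specs


def generate_cases(n_labeled: int, n_unlabeled: int, seed: int = 0,
                   shape: tuple[int, int, int] = (32, 128, 128),
                   radii_range_mm: tuple[float, float] = (8.0, 16.0),
                   ) -> list[LabeledCase | UnlabeledCase]:
    """In-memory cohort: labeled cases first, then unlabeled, deterministically."""
    cases = [generate_phantom(s)
             for s in _cohort_specs(n_labeled, n_unlabeled, seed, shape, radii_range_mm)]
    for i, case in enumerate(cases):
        case.patient_id = f"case-{i:03d}"
        case.volume.patient_id = case.patient_id
    return cases


def generate_cohort(n_labeled: int = DEFAULT_N_LABELED,
                    n_unlabeled: int = DEFAULT_N_UNLABELED,
                    out_dir: str | Path = "cohort", seed: int = 0,
                    shape: tuple[int, int, int] = (32, 128, 128),
                    radii_range_mm: tuple[float, float] = (8.0, 16.0),
                    ) -> pd.DataFrame:
    """Write a cohort to ``out_dir`` as NIfTI and return the manifest.

    Labeled cases get ``<id>.nii.gz`` plus ``<id>_mask.nii.gz``; unlabeled
    cases a bare volume.  The manifest (also written as ``manifest.csv``)
    has one row per case: patient_id, volume_path, mask_path, tumor_voxels.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in generate_cases(n_labeled, n_unlabeled, seed, shape, radii_range_mm):
        pid = case.patient_id
        vol_path = out / f"{pid}.nii.gz"
        save_nifti(vol_path, case.volume.voxels, case.volume.spacing_mm)
        mask_path, n_vox = "", 0
        if isinstance(case, LabeledCase):
            mask_path = out / f"{pid}_mask.nii.gz"
            save_nifti(mask_path, case.mask.voxels, case.mask.spacing_mm)
            n_vox = int(case.mask.voxels.sum())
        rows.append({"patient_id": pid, "volume_path": str(vol_path),
                     "mask_path": str(mask_path), "tumor_voxels": n_vox})
    manifest = pd.DataFrame(rows, columns=["patient_id", "volume_path",
                                           "mask_path", "tumor_voxels"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
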