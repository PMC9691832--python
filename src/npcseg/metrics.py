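"""Segmentation evaluation: five overlap metrics, two surface-distance
metrics, fold aggregation, and the labeled-data-efficiency comparison.

With A the predicted voxel set and B the reference (ground-truth) set, the
overlap metrics, reported as percentages:

* DSC  = 200 |A∩B| / (|A| + |B|)      (Dice similarity coefficient)
* IoU  = 100 |A∩B| / |A∪B|            (intersection over union)
* PPV  = 100 |A∩B| / |A|              (precision)
* Sens = 100 |A∩B| / |B|              (recall / true-positive rate)
* RVE  = 100 | |A| - |B| | / |B|      (relative volume error; lower better)

Per sample, DSC and IoU are linked exactly by dsc = 2 iou / (1 + iou) on
the 0-1 scale; averaged over varied cases the mean IoU drops below the
mean DSC because IoU penalizes poor cases harder.

Surface distances are computed exhaustively over border voxels (a voxel of
the mask with a 6-neighbour outside it), converted to millimetres via the
anisotropic voxel spacing using exact Euclidean distance transforms:
ASSD is the symmetric mean of nearest-surface distances, the Hausdorff
distance the maximum over both directed maxima (the exact symmetric
Hausdorff, not a percentile variant).  Distances are undefined when either
mask is empty; such cases are reported as NaN and excluded from
aggregation.

Empty-mask conventions for overlap: both empty -> perfect agreement
(DSC/IoU/PPV/Sens = 100, RVE = 0); exactly one empty -> overlap metrics 0
and RVE = 100 when the prediction is empty (|A|=0) or |A|/|B|-based
otherwise.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "overlap_metrics", "distance_metrics", "evaluate_case",
    "percentage_difference", "aggregate_folds",
    "OVERLAP_METRICS", "DISTANCE_METRICS",
]

OVERLAP_METRICS = ("dsc_pct", "iou_pct", "ppv_pct", "sensitivity_pct", "rve_pct")
DISTANCE_METRICS = ("assd_mm", "hausdorff_mm")


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def overlap_metrics(pred: np.ndarray, gt: np.ndarray) -> dict[str, float]:
    """DSC / IoU / PPV / sensitivity / RVE as percentages (see module docs)."""
    a, b = _as_bool(pred), _as_bool(gt)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    inter = int((a & b).sum())
    if na == 0 and nb == 0:
        return dict(dsc_pct=100.0, iou_pct=100.0, ppv_pct=100.0,
                    sensitivity_pct=100.0, rve_pct=0.0)
    union = na + nb - inter
    return dict(
        dsc_pct=200.0 * inter / (na + nb),
        iou_pct=100.0 * inter / union,
        ppv_pct=100.0 * inter / na if na else 0.0,
        sensitivity_pct=100.0 * inter / nb if nb else 0.0,
        rve_pct=100.0 * abs(na - nb) / nb if nb else 100.0,
    )


def _surface(mask: np.ndarray) -> np.ndarray:
    """Border voxels: mask voxels with a 6-connected neighbour outside."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0)
    return mask & ~eroded


def distance_metrics(pred: np.ndarray, gt: np.ndarray,
                     spacing_mm: tuple[float, float, float],
                     ) -> dict[str, float]:
    """ASSD and symmetric Hausdorff distance in millimetres.

    Either mask empty -> both reported as NaN with a warning (no surface to
    measure from); callers should exclude such cases from aggregation.
    """
    a, b = _as_bool(pred), _as_bool(gt)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        warnings.warn("empty mask: surface distances undefined, reporting NaN",
                      stacklevel=2)
        return dict(assd_mm=float("nan"), hausdorff_mm=float("nan"))
    sa, sb = _surface(a), _surface(b)
    # exact anisotropic EDT to the *other* surface, evaluated on this surface
    d_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing_mm)[sa]
    d_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing_mm)[sb]
    assd = (d_to_b.sum() + d_to_a.sum()) / (d_to_b.size + d_to_a.size)
    hd = max(d_to_b.max(), d_to_a.max())
    return dict(assd_mm=float(assd), hausdorff_mm=float(hd))


def evaluate_case(pred: np.ndarray, gt: np.ndarray,
                  spacing_mm: tuple[float, float, float]) -> dict[str, float]:
    """All seven metrics for one case (distances NaN if a mask is empty)."""
    out = overlap_metrics(pred, gt)
    a, b = _as_bool(pred), _as_bool(gt)
    if a.any() and b.any():
        out.update(distance_metrics(pred, gt, spacing_mm))
    else:
        out.update(assd_mm=float("nan"), hausdorff_mm=float("nan"))
    return out


def percentage_difference(frozen_value: float, full_value: float) -> float:
    """Signed relative difference of the frozen-encoder result vs the full
    model, as a percentage of the full-model value, rounded to 2 decimals."""
    if full_value == 0:
        raise ZeroDivisionError("full-model value must be non-zero")
    return round(100.0 * (frozen_value - full_value) / full_value, 2)


def aggregate_folds(per_case_reports: list[dict[str, float]] | pd.DataFrame,
                    grouping: str | None = None) -> pd.DataFrame:
    """Mean +/- sample standard deviation per metric.

    ``per_case_reports`` is a list of metric dicts (optionally carrying a
    grouping key such as "fold", "scale" or "model") or an equivalent
    DataFrame.  Returns a table indexed by group (a single "all" row when
    ungrouped) with a ``<metric>_mean``, ``<metric>_std`` column pair and a
    formatted "mean ± std" string column per metric.  NaN entries (e.g.
    undefined distances) are excluded per metric; a single value has std 0.
    """
    df = pd.DataFrame(per_case_reports)
    if df.empty:
        raise ValueError("no reports to aggregate")
    metric_cols = [c for c in df.columns if df[c].dtype.kind in "fi"
                   and c != grouping]
    groups = df.groupby(grouping) if grouping else [("all", df)]
    rows = {}
    for key, sub in groups:
        row = {}
        for c in metric_cols:
            vals = sub[c].dropna().to_numpy(dtype=float)
            mean = vals.mean() if vals.size else float("nan")
            std = vals.std(ddof=1) if vals.size > 1 else 0.0
            row[f"{c}_mean"] = mean
            row[f"{c}_std"] = std
            row[c] = f"{mean:.2f} ± {std:.2f}"
        rows[key] = row
    return pd.DataFrame.from_dict(rows, orient="index")
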