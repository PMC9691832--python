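"""Whole-volume prediction, five-model probability averaging, post-processing.

At test time each model sees the fixed, uncropped normalized volume through
sliding-window inference: windows of the training patch size with 50%
overlap are scored independently and overlapping tumor probabilities are
averaged, yielding a probability map the size of the input.  The five
per-scale models' maps are then combined by a voxelwise arithmetic mean.

The final binary mask is produced by thresholding at 0.5 and a cleanup
chain that encodes the one-primary-tumor prior: one in-plane morphological
erosion then dilation (cross-shaped element) to shave spurious edges,
per-slice retention of the largest 2-D connected region, and finally
retention of the single largest 3-D connected component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import NormalizedVolume

__all__ = ["ProbabilityMap", "SegmentationMask",
           "predict_volume", "ensemble_average", "postprocess"]

# in-plane 4-neighbour cross; no coupling across slices
_INPLANE_CROSS = np.array([[[0, 1, 0], [1, 1, 1], [0, 1, 0]]], dtype=bool)
_CONN6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class ProbabilityMap:
    """Per-voxel tumor probability aligned to its source volume."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    model_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SegmentationMask:
    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(np.uint8)
        if not np.isin(self.voxels, (0, 1)).all():
            raise ValueError("segmentation mask must be binary")


def _window_starts(dim: int, win: int, stride: int) -> list[int]:
    if win >= dim:
        return [0]
    starts = list(range(0, dim - win + 1, stride))
    if starts[-1] != dim - win:
        starts.append(dim - win)
    return starts


def predict_volume(model, vol: NormalizedVolume,
                   window: tuple[int, int, int] | None = None,
                   overlap: float = 0.5, model_id: str = "") -> ProbabilityMap:
    """Sliding-window tumor-probability inference over a whole volume.

    ``window`` defaults to the full volume (single pass).  Windows slide
    with ``overlap`` fraction (50% by default); overlapping probabilities
    are averaged.  A window exceeding the volume is handled by the model's
    internal padding, so output shape always equals input shape.
    """
    x = vol.voxels
    shape = x.shape
    if window is None:
        window = shape
    win = tuple(min(w, s) for w, s in zip(window, shape))
    strides = tuple(max(1, int(w * (1.0 - overlap))) for w in win)
    acc = np.zeros(shape)
    cnt = np.zeros(shape)
    for z0 in _window_starts(shape[0], win[0], strides[0]):
        for y0 in _window_starts(shape[1], win[1], strides[1]):
            for x0 in _window_starts(shape[2], win[2], strides[2]):
                sl = (slice(z0, z0 + win[0]), slice(y0, y0 + win[1]),
                      slice(x0, x0 + win[2]))
                patch = x[sl][None, None]
                acc[sl] += model.predict_proba(patch)[0]
                cnt[sl] += 1.0
    return ProbabilityMap(acc / cnt, vol.spacing_mm, model_id)


def ensemble_average(maps: list[ProbabilityMap]) -> ProbabilityMap:
    """Voxelwise arithmetic mean of per-model probability maps."""
    if not maps:
        raise ValueError("need at least one probability map")
    shape, spacing = maps[0].values.shape, maps[0].spacing_mm
    for m in maps[1:]:
        if m.values.shape != shape or m.spacing_mm != spacing:
            raise ValueError("probability maps must share shape and spacing")
    mean = np.mean([m.values for m in maps], axis=0)
    return ProbabilityMap(mean, spacing, model_id="ensemble")


def _largest_component(mask: np.ndarray, structure: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=structure)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def postprocess(prob_map: ProbabilityMap, threshold: float = 0.5,
                morphology_iterations: int = 1) -> SegmentationMask:
    """Threshold and clean a probability map into the final binary mask.

    Steps, in order: (1) binarize at ``>= threshold``; (2) in-plane erosion
    then dilation with a cross element, ``morphology_iterations`` each (0
    disables); (3) per slice, keep only the largest 2-D connected region;
    (4) keep only the largest 3-D connected component.  An empty output is
    legitimate (no tumor detected).
    """
    mask = prob_map.values >= threshold
    if mask.any() and morphology_iterations > 0:
        mask = ndimage.binary_erosion(mask, structure=_INPLANE_CROSS,
                                      iterations=morphology_iterations)
        mask = ndimage.binary_dilation(mask, structure=_INPLANE_CROSS,
                                       iterations=morphology_iterations)
    if mask.any():
        struct2d = ndimage.generate_binary_structure(2, 1)
        for z in range(mask.shape[0]):
            if mask[z].any():
                mask[z] = _largest_component(mask[z], struct2d)
        mask = _largest_component(mask, _CONN6)
    return SegmentationMask(mask.astype(np.uint8), prob_map.spacing_mm)
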