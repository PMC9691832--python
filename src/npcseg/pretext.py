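"""Self-supervision task construction: 3-D rotation and relative patch location.

Both pretext tasks are posed as multi-class classification over transforms
of unlabeled volumes, so an encoder can be pretrained without any tumor
delineations:

* **Rotation** — the volume is rotated by 0, 90, 180 or 270 degrees about
  one of the three grid axes.  0 degrees is the same volume whatever the
  axis, so there are 10 distinct classes: class 0 is the identity and
  classes 1-9 enumerate {90, 180, 270} x {z-axis, y-axis, x-axis} with the
  angle varying fastest.  Rotations are implemented as axis transpositions
  plus reversals (``np.rot90``), i.e. lossless index permutations, which is
  why input volumes must be cubes in voxel space.

* **Relative patch location (RPL)** — the volume is tiled into a 3x3x3 grid
  of 27 non-overlapping patches; the central patch is the anchor and a
  query patch drawn from the remaining 26 must be localized.  Labels index
  the non-central cells in linear (slice, row, col) order skipping the
  center, a bijection onto 0..25.

The two task losses are blended as ``alpha * L_RPL + (1 - alpha) * L_rot``;
``alpha`` defaults to 0.5 (an even blend — the balance between the tasks is
a free parameter here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "N_ROTATION_CLASSES", "N_RPL_CLASSES", "DEFAULT_ALPHA",
    "RotationSample", "RPLSample", "PretextLoss",
    "rotate_volume", "inverse_rotation_class", "sample_rotation",
    "partition_rpl", "sample_rpl", "rpl_loss", "combined_loss",
]

N_ROTATION_CLASSES = 10
N_RPL_CLASSES = 26
DEFAULT_ALPHA = 0.5

# class k >= 1 decodes to (axis index, quarter turns): axes in (z, y, x)
# order, angles 90/180/270 varying fastest.  np.rot90 plane per axis:
# z-axis rotations act in the (row, col) plane, etc.
_ROT_PLANES = {0: (1, 2), 1: (0, 2), 2: (0, 1)}


def _decode(label: int) -> tuple[int, int]:
    if not 0 < label < N_ROTATION_CLASSES:
        raise ValueError(f"rotation class must be in 1..9, got {label}")
    return (label - 1) // 3, (label - 1) % 3 + 1  # (axis, k quarter-turns)


def rotate_volume(volume: np.ndarray, label: int) -> np.ndarray:
    """Apply the rotation encoded by ``label`` (0 = identity) to a cube."""
    if label == 0:
        return volume.copy()
    axis, k = _decode(label)
    if len(set(volume.shape)) != 1:
        raise ValueError(f"rotation classes need a cubic volume, got {volume.shape}")
    return np.ascontiguousarray(np.rot90(volume, k, axes=_ROT_PLANES[axis]))


def inverse_rotation_class(label: int) -> int:
    """The class whose rotation undoes ``label``'s (classes form a closed set)."""
    if label == 0:
        return 0
    axis, k = _decode(label)
    return 1 + axis * 3 + (4 - k) - 1


@dataclass
class RotationSample:
    volume: np.ndarray
    label: int

    def __post_init__(self) -> None:
        if not 0 <= self.label < N_ROTATION_CLASSES:
            raise ValueError(f"rotation label out of range: {self.label}")


@dataclass
class RPLSample:
    anchor: np.ndarray
    query: np.ndarray
    label: int
    grid_origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if not 0 <= self.label < N_RPL_CLASSES:
            raise ValueError(f"RPL label out of range: {self.label}")


@dataclass
class PretextLoss:
    """Record of one combined-loss evaluation; ``total`` is derived."""

    l_rpl: float
    l_rot: float
    alpha: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        self.total = self.alpha * self.l_rpl + (1.0 - self.alpha) * self.l_rot


def sample_rotation(volume: np.ndarray, rng: np.random.Generator) -> RotationSample:
    """Draw a class uniformly over the 10 orientations and rotate losslessly."""
    label = int(rng.integers(0, N_ROTATION_CLASSES))
    return RotationSample(rotate_volume(volume, label), label)


def partition_rpl(volume: np.ndarray) -> tuple[list[np.ndarray], int,
                                               tuple[int, int, int]]:
    """Tile a volume into 27 equal non-overlapping patches.

    Each axis is divided by 3 (floor); any remainder is trimmed equally
    from both ends (extra voxel from the trailing end when odd).  Returns
    (patches in linear (slice, row, col) cell order, central cell index,
    grid origin offset).
    """
    if any(s < 3 for s in volume.shape):
        raise ValueError(f"each dimension must be >= 3, got {volume.shape}")
    sizes = tuple(s // 3 for s in volume.shape)
    origin = tuple((s - 3 * sz) // 2 for s, sz in zip(volume.shape, sizes))
    patches = []
    for iz in range(3):
        for iy in range(3):
            for ix in range(3):
                sl = tuple(slice(o + i * sz, o + (i + 1) * sz)
                           for o, i, sz in zip(origin, (iz, iy, ix), sizes))
                patches.append(np.ascontiguousarray(volume[sl]))
    return patches, 13, origin


def cell_to_label(cell_index: int) -> int:
    """Map a 3x3x3 linear cell index (excluding 13) to an RPL class 0..25."""
    if cell_index == 13:
        raise ValueError("the central cell is the anchor, never a query")
    if not 0 <= cell_index < 27:
        raise ValueError(f"cell index out of range: {cell_index}")
    return cell_index if cell_index < 13 else cell_index - 1


def label_to_cell(label: int) -> int:
    if not 0 <= label < N_RPL_CLASSES:
        raise ValueError(f"RPL label out of range: {label}")
    return label if label < 13 else label + 1


def sample_rpl(volume: np.ndarray, rng: np.random.Generator) -> RPLSample:
    """Partition and draw a query uniformly from the 26 non-central patches."""
    patches, center, origin = partition_rpl(volume)
    label = int(rng.integers(0, N_RPL_CLASSES))
    return RPLSample(patches[center], patches[label_to_cell(label)], label, origin)


def rpl_loss(scores: np.ndarray, label: int) -> float:
    """Negative log-probability of the true cell under a softmax of the scores."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (N_RPL_CLASSES,):
        raise ValueError(f"expected {N_RPL_CLASSES} scores, got {scores.shape}")
    if not 0 <= label < N_RPL_CLASSES:
        raise ValueError(f"label out of range: {label}")
    z = scores - scores.max()
    return float(np.log(np.exp(z).sum()) - z[label])


def combined_loss(l_rpl: float, l_rot: float, alpha: float = DEFAULT_ALPHA) -> float:
    """Weighted blend ``alpha * l_rpl + (1 - alpha) * l_rot``."""
    return PretextLoss(l_rpl, l_rot, alpha).total
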