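"""Training protocols: supervised segmentation, self-supervised pretraining,
frozen-encoder multi-decoder finetuning, 7-fold cross-validation, and the
labeled-data-efficiency experiment.

The reference protocol trains with Adam from an initial learning rate of
1e-3, decayed stepwise every 150 epochs (multiply-by-0.1 with a floor of
1e-4 — the decay factor and floor are configurable), for 900 epochs at
batch size 32, drawing a random sub-volume patch from a patient volume at
every iteration.  Cross-validation is 7-fold over 63 patients: each fold
holds out 9 patients for testing and splits the remaining 54 into 43
training / 11 validation (an 80/20 split, flooring the training share).

Everything here is deterministic under the config seed: data order, patch
placement, augmentation and weight initialization all derive from seeded
numpy generators, so two runs with identical seeds produce identical
weights.

Desk-scale defaults: the full-protocol numbers above are preserved in
``TrainConfig`` for completeness, while the smoke-scale experiment
functions (``ssl_benefit_trial``) use small phantoms, ``base_width=4``
networks and short schedules so the whole pipeline runs on one CPU in
minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import phantom
from .inference import predict_volume, postprocess
from .metrics import overlap_metrics, percentage_difference
from .model import (ModelConfig, PretextHeads, UNet25D, attach_pretext_heads,
                    build_unet25d, freeze_encoder)
from .nn import Adam, softmax
from .preprocess import resample_to_spacing, window_and_normalize
from .pretext import PretextLoss, sample_rotation, sample_rpl
from .volume import NormalizedVolume

__all__ = [
    "TrainConfig", "FoldSplit", "TrainingHistory",
    "kfold_split", "train_supervised", "pretrain_ssl", "rotation_accuracy",
    "finetune_decoders", "data_efficiency_experiment", "ssl_benefit_trial",
    "cross_entropy", "seg_loss_and_grad", "learning_rate",
]

Case = tuple[np.ndarray, np.ndarray]  # (normalized image, binary mask)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule and sampling parameters (defaults = full protocol)."""

    lr_initial: float = 1e-3
    lr_step_epochs: int = 150
    lr_decay_factor: float = 0.1
    lr_floor: float = 1e-4
    epochs: int = 900
    batch_size: int = 32
    patch_size: tuple[int, int, int] = (8, 32, 32)
    steps_per_epoch: int | None = None
    seed: int = 0
    alpha: float = 0.5               # pretext blend weight
    seg_loss: str = "ce+dice"
    fg_bias: float = 0.5             # fraction of patches forced to contain tumor
    augment_flips: bool = True
    rot_patch_size: int = 16         # cube edge for rotation pretext patches
    rpl_crop_size: tuple[int, int, int] = (12, 24, 24)

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


@dataclass
class TrainingHistory:
    epochs: list[int] = field(default_factory=list)
    losses: list[float] = field(default_factory=list)
    lrs: list[float] = field(default_factory=list)

    def record(self, epoch: int, loss: float, lr: float) -> None:
        if self.epochs and epoch <= self.epochs[-1]:
            raise ValueError("epochs must be recorded monotonically")
        self.epochs.append(epoch)
        self.losses.append(float(loss))
        self.lrs.append(float(lr))


def kfold_split(patient_ids: Sequence[str], k: int = 7, seed: int = 0,
                ) -> list[FoldSplit]:
    """Deterministic k-fold partition with an 80/20 train/val split per fold.

    Test folds are dealt round-robin from a seeded shuffle (sizes differ by
    at most one when ids don't divide evenly); the remaining pool is split
    floor(0.8 n) train / rest val.  With 63 ids and k=7 every test fold has
    exactly 9 ids and each pool of 54 splits 43/11.
    """
    ids = list(patient_ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the number of ids ({len(ids)})")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    test_folds: list[list[str]] = [order[i::k] for i in range(k)]
    splits = []
    for f in range(k):
        pool = [pid for g, fold in enumerate(test_folds) for pid in fold if g != f]
        pool = [pool[i] for i in rng.permutation(len(pool))]
        n_train = int(np.floor(0.8 * len(pool)))
        splits.append(FoldSplit(f, tuple(pool[:n_train]), tuple(pool[n_train:]),
                                tuple(test_folds[f])))
    return splits


def learning_rate(config: TrainConfig, epoch: int) -> float:
    """Stepped schedule: initial rate decayed every ``lr_step_epochs``, floored."""
    lr = config.lr_initial * config.lr_decay_factor ** (epoch // config.lr_step_epochs)
    return max(lr, config.lr_floor)


# ---- losses --------------------------------------------------------------

def cross_entropy(scores: np.ndarray, labels: np.ndarray,
                  ) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy over rows; returns (loss, d loss/d scores)."""
    n = scores.shape[0]
    p = softmax(scores, axis=1)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


def seg_loss_and_grad(logits: np.ndarray, labels: np.ndarray,
                      kind: str = "ce+dice") -> tuple[float, np.ndarray]:
    """Supervised segmentation loss: per-voxel cross-entropy, optionally plus
    a soft-Dice term on the tumor channel, with its analytic logit gradient.

    ``logits`` is (N, 2, D, H, W), ``labels`` (N, D, H, W) in {0, 1}.
    """
    if kind not in ("ce", "ce+dice"):
        raise ValueError(f"unknown segmentation loss {kind!r}")
    n_vox = labels.size
    p = softmax(logits, axis=1)
    onehot = np.stack([1 - labels, labels], axis=1).astype(float)
    eps = 1e-12
    ce = float(-(onehot * np.log(p + eps)).sum() / n_vox)
    grad = (p - onehot) / n_vox
    loss = ce
    if kind == "ce+dice":
        t = p[:, 1]
        y = labels.astype(float)
        smooth = 1.0
        inter = float((t * y).sum())
        denom = float(t.sum() + y.sum()) + smooth
        dice = (2.0 * inter + smooth) / denom
        loss += 1.0 - dice
        # d(1 - dice)/dt, then chain through the 2-class softmax
        dl_dt = -(2.0 * y * denom - (2.0 * inter + smooth)) / denom ** 2
        grad[:, 0] += dl_dt * t * (0.0 - p[:, 0])
        grad[:, 1] += dl_dt * t * (1.0 - t)
    return loss, grad


# ---- patch sampling ------------------------------------------------------

def _contained_offset(rng: np.random.Generator, voxel: int, size: int,
                      dim: int) -> int:
    lo = max(0, voxel - size + 1)
    hi = min(voxel, dim - size)
    if hi < lo:
        lo = hi = int(np.clip(voxel - size // 2, 0, dim - size))
    return int(rng.integers(lo, hi + 1))


def _sample_patch(rng: np.random.Generator, img: np.ndarray, mask: np.ndarray,
                  size: tuple[int, int, int], fg_bias: float,
                  ) -> tuple[np.ndarray, np.ndarray]:
    size = tuple(min(s, d) for s, d in zip(size, img.shape))
    fg = mask.any() and rng.random() < fg_bias
    if fg:
        idx = np.argwhere(mask)
        vz, vy, vx = idx[rng.integers(len(idx))]
        off = tuple(_contained_offset(rng, v, s, d)
                    for v, s, d in zip((vz, vy, vx), size, img.shape))
    else:
        off = tuple(int(rng.integers(0, d - s + 1))
                    for s, d in zip(size, img.shape))
    sl = tuple(slice(o, o + s) for o, s in zip(off, size))
    return img[sl], mask[sl]


def _min_case_shape(cases: Sequence[Case]) -> tuple[int, int, int]:
    shapes = np.array([c[0].shape for c in cases])
    return tuple(int(v) for v in shapes.min(axis=0))


# ---- supervised training -------------------------------------------------

def train_supervised(model: UNet25D, cases: Sequence[Case], config: TrainConfig,
                     ) -> tuple[UNet25D, TrainingHistory]:
    """Patch-based supervised training with Adam and the stepped schedule.

    ``cases`` are (normalized image, binary mask) pairs.  Every iteration
    draws ``batch_size`` random patches (biased to contain tumor with
    probability ``fg_bias``), optionally flip-augmented.  Frozen layers are
    skipped by the optimizer, so the same routine trains full models and
    frozen-encoder models alike.  Raises on non-finite loss.
    """
    if not cases:
        raise ValueError("no training cases")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.all_layers(), lr=config.lr_initial)
    steps = config.steps_per_epoch or max(1, len(cases) // config.batch_size)
    eff = tuple(min(p, m) for p, m in zip(config.patch_size, _min_case_shape(cases)))
    history = TrainingHistory()
    for epoch in range(config.epochs):
        opt.lr = learning_rate(config, epoch)
        epoch_losses = []
        for _ in range(steps):
            imgs, labs = [], []
            for _ in range(config.batch_size):
                img, lab = _sample_patch(rng, *cases[int(rng.integers(len(cases)))],
                                         eff, config.fg_bias)
                if config.augment_flips:
                    for ax in range(3):
                        if rng.random() < 0.5:
                            img, lab = np.flip(img, ax), np.flip(lab, ax)
                imgs.append(img)
                labs.append(lab)
            x = np.stack(imgs)[:, None].astype(np.float64)
            y = np.stack(labs).astype(np.int64)
            logits = model.forward(x, train=True)
            loss, dlogits = seg_loss_and_grad(logits, y, config.seg_loss)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_losses.append(loss)
        history.record(epoch, float(np.mean(epoch_losses)), opt.lr)
    return model, history


# ---- self-supervised pretraining ----------------------------------------

def _random_block(rng: np.random.Generator, vol: np.ndarray,
                  size: tuple[int, int, int]) -> np.ndarray:
    size = tuple(min(s, d) for s, d in zip(size, vol.shape))
    off = tuple(int(rng.integers(0, d - s + 1)) for s, d in zip(size, vol.shape))
    sl = tuple(slice(o, o + s) for o, s in zip(off, size))
    return vol[sl]


def pretrain_ssl(model: UNet25D, heads: PretextHeads,
                 volumes: Sequence[np.ndarray], config: TrainConfig,
                 ) -> tuple[UNet25D, list[PretextLoss]]:
    """Pretrain the encoder on unlabeled volumes with the blended pretext loss.

    Each step draws a batch of cubic patches for the rotation task and a
    batch of 3x3x3-partitioned crops for relative patch location; both are
    pushed through the shared encoder (anchor and query stacked in one
    batch), the per-task cross-entropies are weighted by ``alpha`` and a
    single Adam update is applied to encoder + heads.  A task with zero
    weight is skipped entirely, so with ``alpha=0`` the RPL head never
    touches encoder gradients.  Returns the model (decoder untouched) and
    the per-epoch loss records; the heads are the caller's to discard.
    """
    if not volumes:
        raise ValueError("no unlabeled volumes")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.encoder_layers() + heads.layers(), lr=config.lr_initial)
    steps = config.steps_per_epoch or max(1, len(volumes) // config.batch_size)
    alpha = config.alpha
    cube = (config.rot_patch_size,) * 3
    history: list[PretextLoss] = []
    for epoch in range(config.epochs):
        opt.lr = learning_rate(config, epoch)
        e_rot, e_rpl = [], []
        for _ in range(steps):
            opt.zero_grad()
            l_rot = l_rpl = 0.0
            if alpha < 1.0:  # rotation task
                samples = [sample_rotation(
                    _random_block(rng, volumes[int(rng.integers(len(volumes)))], cube),
                    rng) for _ in range(config.batch_size)]
                x = np.stack([s.volume for s in samples])[:, None]
                labels = np.array([s.label for s in samples])
                _, bot = model.encode(x, train=True)
                pooled = heads.gap.forward(bot, train=True)
                scores = heads.rotation_scores(pooled, train=True)
                l_rot, dscores = cross_entropy(scores, labels)
                dbot = heads.gap.backward(
                    heads.rotation_backward(dscores * (1.0 - alpha)))
                model.backward_encoder(dbot)
            if alpha > 0.0:  # relative patch location task
                samples = [sample_rpl(
                    _random_block(rng, volumes[int(rng.integers(len(volumes)))],
                                  config.rpl_crop_size),
                    rng) for _ in range(config.batch_size)]
                anchors = np.stack([s.anchor for s in samples])[:, None]
                queries = np.stack([s.query for s in samples])[:, None]
                labels = np.array([s.label for s in samples])
                _, bot = model.encode(np.concatenate([anchors, queries]), train=True)
                pooled = heads.gap.forward(bot, train=True)
                b = len(samples)
                scores = heads.rpl_scores(pooled[:b], pooled[b:], train=True)
                l_rpl, dscores = cross_entropy(scores, labels)
                da, dq = heads.rpl_backward(dscores * alpha)
                dbot = heads.gap.backward(np.concatenate([da, dq], axis=0))
                model.backward_encoder(dbot)
            opt.step()
            e_rot.append(l_rot)
            e_rpl.append(l_rpl)
        history.append(PretextLoss(float(np.mean(e_rpl)), float(np.mean(e_rot)),
                                   alpha))
    return model, history


def rotation_accuracy(model: UNet25D, heads: PretextHeads,
                      volumes: Sequence[np.ndarray], n_samples: int = 64,
                      seed: int = 0, cube: int = 16) -> float:
    """Held-out rotation-classification accuracy (chance level is 1/10)."""
    rng = np.random.default_rng(seed)
    correct = 0
    for _ in range(n_samples):
        s = sample_rotation(
            _random_block(rng, volumes[int(rng.integers(len(volumes)))],
                          (cube,) * 3), rng)
        _, bot = model.encode(s.volume[None, None], train=False)
        pooled = heads.gap.forward(bot, train=False)
        pred = int(np.argmax(heads.rotation_scores(pooled, train=False)))
        correct += pred == s.label
    return correct / n_samples


# ---- frozen-encoder ensemble finetuning ----------------------------------

def _share_encoder(source: UNet25D, member_seed: int) -> UNet25D:
    """A new model whose encoder objects ARE the source's (shared weights),
    with a freshly initialized decoder."""
    member = UNet25D(source.config, seed=member_seed)
    member.enc_blocks = source.enc_blocks
    member.pools = source.pools
    member.bottleneck = source.bottleneck
    return member


def finetune_decoders(model: UNet25D, multiscale_datasets: dict[str, Sequence[Case]],
                      config: TrainConfig) -> dict[str, UNet25D]:
    """Train one decoder per crop scale on top of a single frozen encoder.

    The encoder (including bottleneck) of ``model`` is frozen and shared by
    reference across all returned models, so its weights are bit-identical
    before and after finetuning and across ensemble members; each member
    gets an independently initialized, independently trained decoder.
    """
    freeze_encoder(model)
    members: dict[str, UNet25D] = {}
    for i, (scale_name, cases) in enumerate(multiscale_datasets.items()):
        member = _share_encoder(model, member_seed=config.seed + 101 + i)
        member_cfg = replace(config, seed=config.seed + 11 * (i + 1))
        train_supervised(member, cases, member_cfg)
        members[scale_name] = member
    return members


# ---- data-efficiency experiment ------------------------------------------

def _mean_test_dsc(model: UNet25D, test_cases: Sequence[Case],
                   spacing: tuple[float, float, float],
                   window: tuple[int, int, int] | None) -> float:
    scores = []
    for img, mask in test_cases:
        pmap = predict_volume(model, NormalizedVolume(img, spacing), window=window)
        pred = postprocess(pmap)
        scores.append(overlap_metrics(pred.voxels, mask)["dsc_pct"])
    return float(np.mean(scores))


def data_efficiency_experiment(labeled_fractions: Sequence[float],
                               train_cases: Sequence[Case],
                               test_cases: Sequence[Case],
                               unlabeled_volumes: Sequence[np.ndarray],
                               model_config: ModelConfig,
                               train_config: TrainConfig,
                               pretrain_config: TrainConfig | None = None,
                               spacing: tuple[float, float, float] = (3.0, 1.0, 1.0),
                               window: tuple[int, int, int] | None = None,
                               ) -> pd.DataFrame:
    """Frozen-SSL-encoder vs from-scratch full model across labeled-data budgets.

    For each fraction f the same f-share of training patients (seeded
    shuffle) is used to train (a) a decoder on a frozen SSL-pretrained
    encoder and (b) a full model from scratch with the identical iteration
    budget; both are scored by mean test DSC.  One row per fraction:
    (fraction, frozen_dsc, full_dsc, percentage_difference).  Pretraining
    is label-free, so the encoder is pretrained once and shared across
    fractions.
    """
    for f in labeled_fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"fractions must lie in (0, 1], got {f}")
        if int(round(f * len(train_cases))) < 1 and f * len(train_cases) <= 0:
            raise ValueError(f"fraction {f} yields zero training cases")
    pre_cfg = pretrain_config or train_config
    base = build_unet25d(model_config, seed=train_config.seed)
    heads = attach_pretext_heads(base, seed=train_config.seed)
    pretrain_ssl(base, heads, unlabeled_volumes, pre_cfg)
    freeze_encoder(base)

    rng = np.random.default_rng(train_config.seed)
    order = rng.permutation(len(train_cases))
    rows = []
    for j, f in enumerate(labeled_fractions):
        n = max(1, int(round(f * len(train_cases))))
        subset = [train_cases[i] for i in order[:n]]
        frozen = _share_encoder(base, member_seed=train_config.seed + 7)
        train_supervised(frozen, subset, train_config)
        full = build_unet25d(model_config, seed=train_config.seed + 1000 + j)
        train_supervised(full, subset, train_config)
        dsc_frozen = _mean_test_dsc(frozen, test_cases, spacing, window)
        dsc_full = _mean_test_dsc(full, test_cases, spacing, window)
        rows.append({
            "fraction": f,
            "frozen_dsc": dsc_frozen,
            "full_dsc": dsc_full,
            "percentage_difference": percentage_difference(dsc_frozen, dsc_full)
            if dsc_full > 0 else float("nan"),
        })
    return pd.DataFrame(rows, columns=["fraction", "frozen_dsc", "full_dsc",
                                       "percentage_difference"])


# ---- scaled-down SSL-benefit trial ---------------------------------------

# Desk-scale study conditions for the phantom experiments: a base_width-4
# network, 400 pretext steps (relative-patch-location crops span most of the
# volume so grid cells carry distinct anatomy), and 300 supervised steps —
# enough for both the decoder-only and the from-scratch arm to converge on
# 64x64x16 phantoms within CPU-minutes.
SMOKE_MODEL = ModelConfig(base_width=4)
SMOKE_PRETRAIN = TrainConfig(epochs=40, steps_per_epoch=10, batch_size=8,
                             lr_initial=1e-3, alpha=0.5, rot_patch_size=16,
                             rpl_crop_size=(12, 48, 48))
SMOKE_TRAIN = TrainConfig(epochs=30, steps_per_epoch=10, batch_size=2,
                          patch_size=(8, 32, 32), lr_initial=1e-3)


def ssl_benefit_trial(seed: int, n_train: int = 16, n_test: int = 4,
                      labeled_fraction: float = 0.2,
                      shape: tuple[int, int, int] = (16, 64, 64),
                      ) -> dict[str, float]:
    """One seeded replicate of the data-efficiency comparison on phantoms.

    Generates ``n_train + n_test`` labeled phantoms, runs the standard
    preprocessing, pretrains an encoder on the training volumes *without*
    their labels, then compares a frozen-encoder decoder against a
    from-scratch full model, both trained on the same ``labeled_fraction``
    share of training phantoms with identical iteration budgets.  Returns
    mean test DSC for both arms.
    """
    cases = phantom.generate_cases(n_train + n_test, 0, seed=seed, shape=shape,
                                   radii_range_mm=(8.0, 14.0))
    prepared: list[Case] = []
    for case in cases:
        vol, mask = resample_to_spacing(case.volume, case.mask)
        norm = window_and_normalize(vol)
        prepared.append((norm.voxels, mask.voxels))
    train_cases, test_cases = prepared[:n_train], prepared[n_train:]
    unlabeled = [img for img, _ in train_cases]

    pre_cfg = replace(SMOKE_PRETRAIN, seed=seed)
    fit_cfg = replace(SMOKE_TRAIN, seed=seed)
    report = data_efficiency_experiment(
        [labeled_fraction], train_cases, test_cases, unlabeled,
        SMOKE_MODEL, fit_cfg, pretrain_config=pre_cfg)
    row = report.iloc[0]
    return {"frozen_dsc": float(row.frozen_dsc), "full_dsc": float(row.full_dsc)}
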