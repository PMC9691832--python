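"""Cross-validation protocol, losses, supervised/SSL training, finetuning."""

from dataclasses import replace

import numpy as np
import pytest

from npcseg import (ModelConfig, TrainConfig, attach_pretext_heads,
                    build_unet25d, count_parameters, finetune_decoders,
                    generate_cases, kfold_split, pretrain_ssl,
                    resample_to_spacing, rotation_accuracy,
                    trainable_parameter_count, train_supervised,
                    window_and_normalize)
from npcseg.training import (cross_entropy, data_efficiency_experiment,
                             learning_rate, seg_loss_and_grad)

TINY = ModelConfig(base_width=2)
FAST = TrainConfig(epochs=2, steps_per_epoch=3, batch_size=2,
                   patch_size=(4, 16, 16), seed=0)


@pytest.fixture(scope="module")
def smoke_cases():
    cases = generate_cases(4, 0, seed=5, shape=(8, 32, 32),
                           radii_range_mm=(5.0, 8.0))
    out = []
    for c in cases:
        vol, mask = resample_to_spacing(c.volume, c.mask)
        out.append((window_and_normalize(vol).voxels, mask.voxels))
    return out


@pytest.fixture(scope="module")
def smoke_volumes(smoke_cases):
    return [img for img, _ in smoke_cases]


# ---- k-fold protocol -----------------------------------------------------

def test_sevenfold_of_63_patients():
    ids = [f"p{i:02d}" for i in range(63)]
    splits = kfold_split(ids, k=7, seed=1)
    assert len(splits) == 7
    for s in splits:
        assert len(s.test_ids) == 9
        assert len(s.train_ids) == 43 and len(s.val_ids) == 11  # floor(0.8*54)
        assert not (set(s.train_ids) | set(s.val_ids)) & set(s.test_ids)
    all_test = [pid for s in splits for pid in s.test_ids]
    assert sorted(all_test) == sorted(ids)  # exhaustive and disjoint


def test_kfold_deterministic_and_remainder_distributed():
    ids = [str(i) for i in range(10)]
    a = kfold_split(ids, k=3, seed=4)
    b = kfold_split(ids, k=3, seed=4)
    assert a == b
    sizes = sorted(len(s.test_ids) for s in a)
    assert sizes == [3, 3, 4]


def test_kfold_rejects_k_larger_than_cohort():
    with pytest.raises(ValueError):
        kfold_split(["a", "b"], k=3)


def test_learning_rate_schedule():
    cfg = TrainConfig()
    assert learning_rate(cfg, 0) == 1e-3
    assert learning_rate(cfg, 149) == 1e-3
    assert learning_rate(cfg, 150) == pytest.approx(1e-4)
    assert learning_rate(cfg, 600) == pytest.approx(1e-4)  # floored


# ---- losses --------------------------------------------------------------

def test_cross_entropy_gradient_matches_finite_difference(rng):
    scores = rng.standard_normal((4, 10))
    labels = rng.integers(0, 10, 4)
    _, grad = cross_entropy(scores, labels)
    eps = 1e-6
    for idx in [(0, 0), (1, 5), (3, 9)]:
        s = scores.copy()
        s[idx] += eps
        lp, _ = cross_entropy(s, labels)
        s[idx] -= 2 * eps
        lm, _ = cross_entropy(s, labels)
        assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)


@pytest.mark.parametrize("kind", ["ce", "ce+dice"])
def test_seg_loss_gradient_matches_finite_difference(kind, rng):
    logits = rng.standard_normal((1, 2, 2, 3, 3))
    labels = (rng.random((1, 2, 3, 3)) > 0.5).astype(np.int64)
    _, grad = seg_loss_and_grad(logits, labels, kind)
    eps = 1e-6
    for idx in [(0, 0, 0, 0, 0), (0, 1, 1, 2, 2), (0, 0, 1, 1, 1)]:
        z = logits.copy()
        z[idx] += eps
        lp, _ = seg_loss_and_grad(z, labels, kind)
        z[idx] -= 2 * eps
        lm, _ = seg_loss_and_grad(z, labels, kind)
        assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)


# ---- supervised training -------------------------------------------------

def test_smoke_training_reduces_loss(smoke_cases):
    model = build_unet25d(TINY, seed=1)
    cfg = replace(FAST, epochs=10, steps_per_epoch=4)
    _, history = train_supervised(model, smoke_cases, cfg)
    assert history.losses[-1] < history.losses[0]
    assert history.lrs[0] == 1e-3


def test_identical_seeds_give_identical_weights(smoke_cases):
    weights = []
    for _ in range(2):
        model = build_unet25d(TINY, seed=3)
        train_supervised(model, smoke_cases, FAST)
        weights.append(np.concatenate(
            [p.ravel() for l in model.all_layers() for p in l.params.values()]))
    assert np.array_equal(weights[0], weights[1])


def test_training_rejects_empty_dataset():
    with pytest.raises(ValueError):
        train_supervised(build_unet25d(TINY), [], FAST)


# ---- SSL pretraining -----------------------------------------------------

def test_pretext_loss_decreases_over_smoke_run(smoke_volumes):
    model = build_unet25d(TINY, seed=2)
    heads = attach_pretext_heads(model, seed=2)
    cfg = replace(FAST, epochs=8, steps_per_epoch=5, batch_size=4,
                  rot_patch_size=8, rpl_crop_size=(6, 24, 24))
    _, history = pretrain_ssl(model, heads, smoke_volumes, cfg)
    assert history[-1].total < history[0].total


def test_rotation_accuracy_beats_chance_after_pretraining(smoke_volumes):
    model = build_unet25d(TINY, seed=4)
    heads = attach_pretext_heads(model, seed=4)
    cfg = replace(FAST, epochs=10, steps_per_epoch=8, batch_size=6,
                  alpha=0.0, rot_patch_size=8)  # rotation task only
    pretrain_ssl(model, heads, smoke_volumes, cfg)
    acc = rotation_accuracy(model, heads, smoke_volumes, n_samples=60,
                            seed=1, cube=8)
    assert acc > 0.1


def test_alpha_zero_never_touches_rpl_head(smoke_volumes):
    model = build_unet25d(TINY, seed=5)
    heads = attach_pretext_heads(model, seed=5)
    before = heads.rpl_fc1.params["w"].copy()
    cfg = replace(FAST, alpha=0.0, rot_patch_size=8)
    pretrain_ssl(model, heads, smoke_volumes, cfg)
    assert np.array_equal(heads.rpl_fc1.params["w"], before)


def test_pretraining_leaves_decoder_untouched(smoke_volumes):
    model = build_unet25d(TINY, seed=6)
    heads = attach_pretext_heads(model, seed=6)
    before = [p.copy() for l in model.decoder_layers() for p in l.params.values()]
    cfg = replace(FAST, rot_patch_size=8, rpl_crop_size=(6, 24, 24))
    pretrain_ssl(model, heads, smoke_volumes, cfg)
    after = [p for l in model.decoder_layers() for p in l.params.values()]
    assert all(np.array_equal(a, b) for a, b in zip(before, after))


# ---- frozen-encoder finetuning -------------------------------------------

def test_finetune_keeps_encoder_weights_bit_identical(smoke_cases):
    model = build_unet25d(TINY, seed=7)
    before = np.concatenate([p.ravel() for l in model.encoder_layers()
                             for p in l.params.values()])
    members = finetune_decoders(model, {"small": smoke_cases[:2],
                                        "large": smoke_cases[2:]}, FAST)
    for member in members.values():
        after = np.concatenate([p.ravel() for l in member.encoder_layers()
                                for p in l.params.values()])
        assert np.array_equal(before, after)


def test_finetuned_members_differ_in_output(smoke_cases, rng):
    model = build_unet25d(TINY, seed=8)
    members = finetune_decoders(model, {"a": smoke_cases[:2],
                                        "b": smoke_cases[2:]}, FAST)
    x = rng.random((1, 1, 4, 16, 16))
    outs = [m.forward(x, train=False) for m in members.values()]
    assert not np.allclose(outs[0], outs[1])


def test_frozen_trainable_count_equals_decoder_partition():
    from npcseg import freeze_encoder
    model = freeze_encoder(build_unet25d(TINY))
    assert trainable_parameter_count(model) == count_parameters(model, "decoder")


# ---- data-efficiency experiment -----------------------------------------

def test_data_efficiency_report_schema(smoke_cases, smoke_volumes):
    report = data_efficiency_experiment(
        [0.5, 1.0], smoke_cases[:3], smoke_cases[3:], smoke_volumes,
        TINY, replace(FAST, epochs=1, steps_per_epoch=1),
        pretrain_config=replace(FAST, epochs=1, steps_per_epoch=1,
                                rot_patch_size=8, rpl_crop_size=(6, 24, 24)))
    assert list(report.columns) == ["fraction", "frozen_dsc", "full_dsc",
                                    "percentage_difference"]
    assert len(report) == 2


def test_data_efficiency_rejects_bad_fraction(smoke_cases, smoke_volumes):
    with pytest.raises(ValueError):
        data_efficiency_experiment([1.5], smoke_cases[:2], smoke_cases[2:],
                                   smoke_volumes, TINY, FAST)
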