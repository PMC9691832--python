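"""Train a small segmentation ensemble on phantoms and evaluate it.

Runs the full supervised path at desk scale (a base_width-4 network, a few
hundred gradient steps): train one model per crop scale on two scales,
predict whole test volumes by sliding window, average the probability
maps, post-process, and report the seven evaluation metrics.  Takes a few
CPU minutes.
"""

from dataclasses import replace

import numpy as np

from npcseg import (GTVMask, ModelConfig, NormalizedVolume, TrainConfig,
                    aggregate_folds, build_unet25d, canonical_scales,
                    crop_multiscale, ensemble_average, evaluate_case,
                    generate_cases, postprocess, predict_volume,
                    resample_to_spacing, train_supervised,
                    window_and_normalize)

SPACING = (3.0, 1.0, 1.0)

cases = []
for c in generate_cases(6, 0, seed=11, shape=(16, 64, 64),
                        radii_range_mm=(8.0, 14.0)):
    vol, mask = resample_to_spacing(c.volume, c.mask)
    cases.append((window_and_normalize(vol).voxels, mask.voxels))
train_cases, test_cases = cases[:4], cases[4:]

cfg = TrainConfig(epochs=15, steps_per_epoch=10, batch_size=2,
                  patch_size=(8, 32, 32), seed=0)
rng = np.random.default_rng(0)
members = []
for i, scale in enumerate(canonical_scales()[1:4:2]):  # small + large
    scaled = []
    for img, mask in train_cases:
        crop = crop_multiscale(NormalizedVolume(img, SPACING),
                               GTVMask(mask, SPACING), scale, rng)
        scaled.append((crop.image, crop.label))
    model = build_unet25d(ModelConfig(base_width=4), seed=i)
    _, hist = train_supervised(model, scaled, replace(cfg, seed=i))
    print(f"{scale.name}: loss {hist.losses[0]:.3f} -> {hist.losses[-1]:.3f}")
    members.append(model)

reports = []
for img, mask in test_cases:
    maps = [predict_volume(m, NormalizedVolume(img, SPACING),
                           window=(8, 32, 32)) for m in members]
    pred = postprocess(ensemble_average(maps))
    reports.append(evaluate_case(pred.voxels, mask, SPACING))

table = aggregate_folds(reports)
cols = ["dsc_pct", "iou_pct", "ppv_pct", "sensitivity_pct", "rve_pct",
        "assd_mm", "hausdorff_mm"]
print("\ntest performance (mean ± sample std over test cases):")
for c in cols:
    print(f"  {c:16s} {table.loc['all', c]}")
print("\nDSC/IoU/PPV/sensitivity are overlap percentages (higher better),")
print("RVE is the relative volume error, ASSD/Hausdorff are surface")
print("distances in mm (lower better).")
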