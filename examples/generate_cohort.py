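"""Generate a small synthetic phantom cohort and inspect its manifest.

Labeled cases carry one irregular hyperintense tumor blob and a binary
mask; unlabeled ("healthy") cases have no tumor and no mask — mirroring a
cohort of delineated patient scans plus extra scans usable only for
self-supervised pretraining.
"""

from pathlib import Path

from npcseg import generate_cohort

out = Path("scratch/example_cohort")
manifest = generate_cohort(n_labeled=4, n_unlabeled=2, out_dir=out, seed=42,
                           shape=(16, 64, 64))
print(manifest.to_string(index=False))
print(f"\n{len(manifest)} cases written to {out}/ as NIfTI volumes.")
print("tumor_voxels is the mask cardinality: 0 marks the unlabeled cases,")
print("so the last two rows are the healthy scans used only for pretraining.")
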