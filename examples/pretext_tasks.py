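"""The two self-supervision tasks built from an unlabeled volume.

Rotation: a cubic patch is rotated by one of 10 orientation classes
(identity, or 90/180/270 degrees about each grid axis) and the encoder must
recover the class.  Relative patch location: the volume is tiled 3x3x3 and
the encoder must say which of the 26 non-central cells a query patch came
from, given the central anchor.  Both are lossless index operations, so
labels are exact.
"""

import numpy as np

from npcseg import (PhantomSpec, combined_loss, generate_phantom,
                    partition_rpl, rpl_loss, sample_rotation, sample_rpl,
                    window_and_normalize)

case = generate_phantom(PhantomSpec(shape=(16, 64, 64), tumor_present=False,
                                    seed=3))
norm = window_and_normalize(case.volume).voxels
rng = np.random.default_rng(0)

cube = norm[:16, 24:40, 24:40]
rot = sample_rotation(cube, rng)
print(f"rotation sample: class {rot.label} of 10 "
      f"(0 = identity; 1-9 = 90/180/270 deg x z/y/x axis)")

patches, center, origin = partition_rpl(norm[:15, :63, :63])
rpl = sample_rpl(norm[:15, :63, :63], rng)
print(f"RPL partition: {len(patches)} patches of {patches[0].shape}, "
      f"anchor = cell {center}; sampled query class {rpl.label} of 26")

uniform = np.zeros(26)
print(f"\nRPL loss at uniform scores: {rpl_loss(uniform, rpl.label):.4f} "
      f"(= ln 26 = {np.log(26):.4f}, the no-information baseline)")
print(f"blended pretext loss at alpha=0.5, L_RPL=2, L_rot=4: "
      f"{combined_loss(2.0, 4.0, 0.5):.1f}")
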