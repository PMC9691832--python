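"""Parameter accounting of the UNet-2.5D and the effect of encoder freezing.

The architecture uses in-plane 3x3x1 convolutions everywhere except the
3x3x3 bottleneck.  Freezing the encoder (including that bottleneck) leaves
only the decoder partition trainable — less than a quarter of the model —
which is what makes the multi-decoder ensemble cheap to finetune.
"""

from npcseg import (ModelConfig, build_unet25d, count_parameters,
                    freeze_encoder, trainable_parameter_count)

model = build_unet25d(ModelConfig())
full = count_parameters(model, "full")
enc = count_parameters(model, "encoder")
dec = count_parameters(model, "decoder")

print("Network setting                Number of parameters")
print(f"Full Model                     {full:>12,}")
print(f"Encoder (incl. 3D bottleneck)  {enc:>12,}")
print(f"Decoder Only (Frozen Encoder)  {dec:>12,}")

freeze_encoder(model)
print(f"\ntrainable after freezing:      {trainable_parameter_count(model):>12,}")
print(f"full/decoder ratio:            {full / dec:>12.2f}  (> 4)")
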