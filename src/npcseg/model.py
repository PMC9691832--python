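"""UNet-2.5D encoder-decoder for volumetric gross-tumor-volume segmentation.

The network is "2.5D": every convolution is in-plane (kernel 3x3 within a
slice, extent 1 across slices) except the bottleneck block, which uses full
3x3x3 convolutions so cross-slice context enters exactly once, at the
coarsest resolution.  This suits anisotropic head CT (3 mm slices vs ~1 mm
in-plane) and keeps the parameter count small enough to train on tens of
labeled cases.

Default layout (``base_width=16, depth=4``):

* encoder: 4 blocks at 16/32/64/128 channels, each two (conv 3x3x1 + batch
  norm + ReLU); 2x2 in-plane max-pool between blocks, 2x2x2 pool into the
  bottleneck;
* bottleneck: two (conv 3x3x3 + batch norm + ReLU) at 128->256->256;
* decoder: learned up-convolution (2x2x2 leaving the bottleneck, 2x2x1
  after) + batch norm + ReLU, skip concatenation, then two (conv 3x3x1 +
  batch norm + ReLU); a final 3x3x1 convolution maps to 2 class channels.

This layout has exactly 3,845,058 learnable scalars, 895,122 of them in the
decoder partition — the published sizes for this architecture — which
``tests`` verify against an independent layer-formula count.

Inputs of arbitrary size are handled by reflect-padding slices to an even
count and rows/cols to a multiple of ``2**depth``, then cropping the output
scores back, so output spatial shape always equals input spatial shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "ModelConfig",
    "UNet25D",
    "PretextHeads",
    "build_unet25d",
    "attach_pretext_heads",
    "count_parameters",
    "freeze_encoder",
    "unfreeze_encoder",
    "trainable_parameter_count",
    "save_model",
    "load_model",
]

N_ROTATION_CLASSES = 10
N_RPL_CLASSES = 26


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; channel width doubles per encoder level."""

    base_width: int = 16
    depth: int = 4
    out_classes: int = 2
    use_bias: bool = True

    def __post_init__(self) -> None:
        if self.base_width < 1 or self.depth < 1 or self.out_classes < 1:
            raise ValueError(f"invalid model config {self}")

    @property
    def bottleneck_channels(self) -> int:
        return self.base_width * 2 ** self.depth

    @property
    def inplane_multiple(self) -> int:
        return 2 ** self.depth

    @property
    def slice_multiple(self) -> int:
        return 2


class _ConvBlock:
    """Two (conv + batch norm + ReLU) stages with a shared kernel shape."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int, int],
                 rng: np.random.Generator, bias: bool) -> None:
        self.layers = [
            nn.Conv3d(c_in, c_out, kernel, rng, bias=bias),
            nn.BatchNorm3d(c_out),
            nn.ReLU(),
            nn.Conv3d(c_out, c_out, kernel, rng, bias=bias),
            nn.BatchNorm3d(c_out),
            nn.ReLU(),
        ]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def param_layers(self) -> list[nn.Layer]:
        return [l for l in self.layers if l.params]


class UNet25D:
    """The segmentation network; see module docstring for the layout."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        w, depth, bias = config.base_width, config.depth, config.use_bias
        ch = [w * 2 ** i for i in range(depth)]
        k2d, k3d = (1, 3, 3), (3, 3, 3)

        self.enc_blocks, self.pools = [], []
        c_prev = 1
        for i, c in enumerate(ch):
            self.enc_blocks.append(_ConvBlock(c_prev, c, k2d, rng, bias))
            self.pools.append(nn.MaxPool3d((2, 2, 2) if i == depth - 1 else (1, 2, 2)))
            c_prev = c
        self.bottleneck = _ConvBlock(ch[-1], 2 * ch[-1], k3d, rng, bias)

        self.ups, self.up_bns, self.up_relus, self.dec_blocks = [], [], [], []
        c_prev = 2 * ch[-1]
        for j, c in enumerate(reversed(ch)):
            factor = (2, 2, 2) if j == 0 else (1, 2, 2)
            self.ups.append(nn.ConvTranspose3d(c_prev, c, factor, rng, bias=bias))
            self.up_bns.append(nn.BatchNorm3d(c))
            self.up_relus.append(nn.ReLU())
            self.dec_blocks.append(_ConvBlock(2 * c, c, k2d, rng, bias))
            c_prev = c
        self.final = nn.Conv3d(ch[0], config.out_classes, k2d, rng, bias=bias)

    # ---- parameter partitions -------------------------------------------
    def encoder_layers(self) -> list[nn.Layer]:
        """Encoder partition: the four 2.5D blocks plus the 3D bottleneck."""
        out: list[nn.Layer] = []
        for blk in self.enc_blocks:
            out.extend(blk.param_layers())
        out.extend(self.bottleneck.param_layers())
        return out

    def decoder_layers(self) -> list[nn.Layer]:
        """Decoder partition: up-convs + their norms, blocks, final classifier."""
        out: list[nn.Layer] = []
        for up, bn, blk in zip(self.ups, self.up_bns, self.dec_blocks):
            out.extend([up, bn])
            out.extend(blk.param_layers())
        out.append(self.final)
        return out

    def all_layers(self) -> list[nn.Layer]:
        return self.encoder_layers() + self.decoder_layers()

    # ---- padding ---------------------------------------------------------
    def _pad(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int, int]]:
        _, _, d, h, w = x.shape
        md, mi = self.config.slice_multiple, self.config.inplane_multiple
        pd, ph, pw = (-d) % md, (-h) % mi, (-w) % mi
        if pd or ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, pd), (0, ph), (0, pw)), mode="reflect")
        return x, (pd, ph, pw)

    # ---- forward / backward ---------------------------------------------
    def encode(self, x: np.ndarray, train: bool = True
               ) -> tuple[list[np.ndarray], np.ndarray]:
        """Run the encoder; returns per-level skip features and bottleneck output.

        ``x`` is (N, 1, D, H, W) and is reflect-padded internally, so any
        patch size works (pretext patches are typically smaller than the
        in-plane multiple).
        """
        x, self._pads = self._pad(x)
        skips = []
        h = x
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = blk.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        return skips, self.bottleneck.forward(h, train)

    def backward_encoder(self, g_bottom: np.ndarray,
                         g_skips: list[np.ndarray] | None = None) -> None:
        """Backpropagate through bottleneck + encoder (skip grads optional)."""
        g = self.bottleneck.backward(g_bottom)
        for i in reversed(range(len(self.enc_blocks))):
            g = self.pools[i].backward(g)
            if g_skips is not None:
                g = g + g_skips[i]
            g = self.enc_blocks[i].backward(g)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Full segmentation pass: (N,1,D,H,W) -> (N,out_classes,D,H,W) scores."""
        orig = x.shape[2:]
        skips, h = self.encode(x, train)
        for j, (up, bn, relu, blk) in enumerate(
                zip(self.ups, self.up_bns, self.up_relus, self.dec_blocks)):
            h = relu.forward(bn.forward(up.forward(h, train), train), train)
            skip = skips[len(skips) - 1 - j]
            h = np.concatenate([skip, h], axis=1)
            h = blk.forward(h, train)
        logits = self.final.forward(h, train)
        return logits[:, :, :orig[0], :orig[1], :orig[2]]

    def backward(self, g_logits: np.ndarray) -> None:
        pd, ph, pw = self._pads
        if pd or ph or pw:
            g_logits = np.pad(g_logits, ((0, 0), (0, 0), (0, pd), (0, ph), (0, pw)))
        g = self.final.backward(g_logits)
        depth = len(self.dec_blocks)
        g_skips: list[np.ndarray | None] = [None] * depth
        for j in reversed(range(depth)):
            g = self.dec_blocks[j].backward(g)
            c_skip = g.shape[1] // 2
            g_skips[depth - 1 - j] = g[:, :c_skip]
            g = self.up_relus[j].backward(g[:, c_skip:])
            g = self.up_bns[j].backward(g)
            g = self.ups[j].backward(g)
        self.backward_encoder(g, g_skips)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode tumor probability, shape (N, D, H, W)."""
        return nn.softmax(self.forward(x, train=False), axis=1)[:, 1]


class PretextHeads:
    """Classification heads for the two self-supervision tasks.

    Both heads read globally average-pooled bottleneck embeddings, so the
    patch size fed to the encoder is free to vary.  The rotation head is a
    single linear map to 10 orientation classes; the relative-patch-location
    head concatenates the anchor and query embeddings and applies a two-layer
    classifier over the 26 grid positions.  Heads are discarded after
    pretraining and are never part of the segmentation parameter partitions.
    """

    def __init__(self, bottleneck_channels: int, seed: int = 0,
                 hidden: int = 64) -> None:
        rng = np.random.default_rng(seed)
        c = bottleneck_channels
        self.gap = nn.GlobalAvgPool()
        self.rot_fc = nn.Linear(c, N_ROTATION_CLASSES, rng)
        self.rpl_fc1 = nn.Linear(2 * c, hidden, rng)
        self.rpl_relu = nn.ReLU()
        self.rpl_fc2 = nn.Linear(hidden, N_RPL_CLASSES, rng)

    def layers(self) -> list[nn.Layer]:
        return [self.rot_fc, self.rpl_fc1, self.rpl_fc2]

    def rotation_scores(self, pooled: np.ndarray, train: bool = True) -> np.ndarray:
        return self.rot_fc.forward(pooled, train)

    def rotation_backward(self, g_scores: np.ndarray) -> np.ndarray:
        return self.rot_fc.backward(g_scores)

    def rpl_scores(self, anchor_emb: np.ndarray, query_emb: np.ndarray,
                   train: bool = True) -> np.ndarray:
        fused = np.concatenate([anchor_emb, query_emb], axis=1)
        h = self.rpl_fc1.forward(fused, train)
        h = self.rpl_relu.forward(h, train)
        return self.rpl_fc2.forward(h, train)

    def rpl_backward(self, g_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        g = self.rpl_fc2.backward(g_scores)
        g = self.rpl_relu.backward(g)
        g = self.rpl_fc1.backward(g)
        c = g.shape[1] // 2
        return g[:, :c], g[:, c:]


def build_unet25d(config: ModelConfig = ModelConfig(), seed: int = 0) -> UNet25D:
    return UNet25D(config, seed=seed)


def attach_pretext_heads(model: UNet25D, seed: int = 0) -> PretextHeads:
    return PretextHeads(model.config.bottleneck_channels, seed=seed)


def count_parameters(model: UNet25D, part: str = "full") -> int:
    """Exact learnable-scalar count of a partition: full | encoder | decoder.

    The encoder partition includes the 3D bottleneck; the decoder partition
    includes up-convolutions with their norm layers, the decoder conv
    blocks, and the final classifier.
    """
    if part == "full":
        layers = model.all_layers()
    elif part == "encoder":
        layers = model.encoder_layers()
    elif part == "decoder":
        layers = model.decoder_layers()
    else:
        raise ValueError(f"unknown partition {part!r}")
    return sum(l.n_params() for l in layers)


def trainable_parameter_count(model: UNet25D) -> int:
    return sum(l.n_params() for l in model.all_layers() if l.trainable)


def freeze_encoder(model: UNet25D) -> UNet25D:
    """Mark encoder (incl. bottleneck) parameters non-trainable.

    All encoder weights (conv kernels, biases, norm gains/shifts) are then
    bit-identical across any subsequent finetuning.  Batch-norm layers keep
    normalizing with batch statistics while training — the conventional
    train-mode behavior of a weight-frozen module — so only their running
    statistic buffers continue to track the finetuning data.
    """
    for layer in model.encoder_layers():
        layer.trainable = False
    return model


def unfreeze_encoder(model: UNet25D) -> UNet25D:
    for layer in model.encoder_layers():
        layer.trainable = True
    return model


# ---- serialization -------------------------------------------------------

def _state_dict(model: UNet25D) -> dict[str, np.ndarray]:
    state: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model.all_layers()):
        for name, p in layer.params.items():
            state[f"layer{i}.{name}"] = p
        if isinstance(layer, nn.BatchNorm3d):
            state[f"layer{i}.running_mean"] = layer.running_mean
            state[f"layer{i}.running_var"] = layer.running_var
    return state


def save_model(model: UNet25D, path: str | Path) -> None:
    """Write weights (.npz) plus a JSON sidecar with config and counts."""
    path = Path(path)
    np.savez(path, **_state_dict(model))
    sidecar = {
        "config": asdict(model.config),
        "parameters": {part: count_parameters(model, part)
                       for part in ("full", "encoder", "decoder")},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> UNet25D:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    model = UNet25D(ModelConfig(**sidecar["config"]))
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    for i, layer in enumerate(model.all_layers()):
        for name in layer.params:
            layer.params[name][...] = data[f"layer{i}.{name}"]
        if isinstance(layer, nn.BatchNorm3d):
            layer.running_mean[...] = data[f"layer{i}.running_mean"]
            layer.running_var[...] = data[f"layer{i}.running_var"]
    return model
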