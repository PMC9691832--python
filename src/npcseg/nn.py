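"""Minimal CPU neural-network layer library used by the segmentation models.

Layers operate on ``(N, C, D, H, W)`` float64 arrays (batch, channel, slice,
row, col) and implement explicit ``forward``/``backward`` passes so the whole
training stack runs on numpy alone.  Each layer caches what its backward pass
needs during ``forward`` and *accumulates* parameter gradients in ``grads``
(callers zero them via the optimizer), which lets a training step sum the
gradients of several forward/backward passes — e.g. the two pretext losses —
before a single optimizer update.

Conventions
-----------
* convolutions are stride-1 with odd kernels and symmetric zero "same"
  padding, so spatial shape is preserved;
* transposed convolutions and max-pools use non-overlapping windows
  (stride == kernel), the only variants the U-Net needs;
* ``trainable=False`` freezes a layer: the optimizer skips its parameters and
  a frozen batch-norm also pins its running statistics and normalizes with
  them even in training mode.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv3d",
    "ConvTranspose3d",
    "BatchNorm3d",
    "ReLU",
    "MaxPool3d",
    "GlobalAvgPool",
    "Linear",
    "Adam",
    "softmax",
]


class Layer:
    """Base class: a parameter dict, a matching grad dict, a trainable flag."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.trainable: bool = True

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def zero_grad(self) -> None:
        for k, g in self.grads.items():
            g[...] = 0.0


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv3d(Layer):
    """Stride-1 'same' 3-D convolution; kernel (kd, kh, kw) must be odd."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int, int],
                 rng: np.random.Generator, bias: bool = True) -> None:
        super().__init__()
        if any(k % 2 == 0 for k in kernel):
            raise ValueError(f"kernel dims must be odd, got {kernel}")
        self.kernel = tuple(kernel)
        self.pad = tuple(k // 2 for k in kernel)
        fan_in = c_in * int(np.prod(kernel))
        self.params["w"] = _he_init(rng, (c_out, c_in, *kernel), fan_in)
        self.grads["w"] = np.zeros_like(self.params["w"])
        if bias:
            self.params["b"] = np.zeros(c_out)
            self.grads["b"] = np.zeros(c_out)
        self._cache: tuple | None = None

    @staticmethod
    def _corr(x: np.ndarray, w: np.ndarray, pad: tuple[int, int, int]) -> np.ndarray:
        """Same-size correlation of (N,C,D,H,W) with (O,C,kd,kh,kw)."""
        xp = np.pad(x, ((0, 0), (0, 0), (pad[0],) * 2, (pad[1],) * 2, (pad[2],) * 2))
        win = sliding_window_view(xp, w.shape[2:], axis=(2, 3, 4))
        out = np.tensordot(win, w, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
        return np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = self._corr(x, self.params["w"], self.pad)
        if "b" in self.params:
            out += self.params["b"][None, :, None, None, None]
        if train:
            self._cache = (x,)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        (x,) = self._cache
        w = self.params["w"]
        pad = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (pad[0],) * 2, (pad[1],) * 2, (pad[2],) * 2))
        win = sliding_window_view(xp, w.shape[2:], axis=(2, 3, 4))
        # (N,O,D,H,W) x (N,C,D,H,W,kd,kh,kw) -> (O,C,kd,kh,kw)
        self.grads["w"] += np.tensordot(gout, win, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
        if "b" in self.params:
            self.grads["b"] += gout.sum(axis=(0, 2, 3, 4))
        # input grad: same-correlation with the spatially flipped, transposed kernel
        w_flip = w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        return self._corr(gout, w_flip, pad)


class ConvTranspose3d(Layer):
    """Learned upsampling with stride == kernel (non-overlapping blocks)."""

    def __init__(self, c_in: int, c_out: int, factor: tuple[int, int, int],
                 rng: np.random.Generator, bias: bool = True) -> None:
        super().__init__()
        self.factor = tuple(factor)
        fan_in = c_in * int(np.prod(factor))
        self.params["w"] = _he_init(rng, (c_in, c_out, *factor), fan_in)
        self.grads["w"] = np.zeros_like(self.params["w"])
        if bias:
            self.params["b"] = np.zeros(c_out)
            self.grads["b"] = np.zeros(c_out)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, _, d, h, w_ = x.shape
        fd, fh, fw = self.factor
        out = np.einsum("ncdhw,coijk->nodihjwk", x, self.params["w"])
        out = out.reshape(n, -1, d * fd, h * fh, w_ * fw)
        if "b" in self.params:
            out += self.params["b"][None, :, None, None, None]
        if train:
            self._cache = (x,)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        (x,) = self._cache
        n, _, d, h, w_ = x.shape
        fd, fh, fw = self.factor
        gr = gout.reshape(gout.shape[0], gout.shape[1], d, fd, h, fh, w_, fw)
        self.grads["w"] += np.einsum("ncdhw,nodihjwk->coijk", x, gr)
        if "b" in self.params:
            self.grads["b"] += gout.sum(axis=(0, 2, 3, 4))
        return np.einsum("nodihjwk,coijk->ncdhw", gr, self.params["w"])


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, D, H, W) with running stats.

    ``trainable=False`` stops gamma/beta updates but — matching the usual
    train-mode behavior of weight-frozen modules — batch statistics are
    still used and running statistics still tracked while training, unless
    ``freeze_stats`` is also set, which pins the layer entirely to its
    stored running statistics.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.freeze_stats = False
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.grads["gamma"] = np.zeros(channels)
        self.grads["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache: tuple | None = None

    def _bc(self, v: np.ndarray) -> np.ndarray:
        return v[None, :, None, None, None]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (0, 2, 3, 4)
        use_batch_stats = train and not self.freeze_stats
        if use_batch_stats:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - self._bc(mean)) / self._bc(std)
        if train:
            self._cache = (xhat, std, use_batch_stats)
        return self._bc(self.params["gamma"]) * xhat + self._bc(self.params["beta"])

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, std, used_batch = self._cache
        axes = (0, 2, 3, 4)
        self.grads["gamma"] += (gout * xhat).sum(axis=axes)
        self.grads["beta"] += gout.sum(axis=axes)
        ghat = gout * self._bc(self.params["gamma"])
        if not used_batch:
            return ghat / self._bc(std)  # running stats are constants
        return (ghat - self._bc(ghat.mean(axis=axes))
                - xhat * self._bc((ghat * xhat).mean(axis=axes))) / self._bc(std)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class MaxPool3d(Layer):
    """Non-overlapping max pooling; input dims must divide the pool factor."""

    def __init__(self, factor: tuple[int, int, int]) -> None:
        super().__init__()
        self.factor = tuple(factor)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, d, h, w = x.shape
        fd, fh, fw = self.factor
        if d % fd or h % fh or w % fw:
            raise ValueError(f"shape {(d, h, w)} not divisible by pool {self.factor}")
        xr = (x.reshape(n, c, d // fd, fd, h // fh, fh, w // fw, fw)
              .transpose(0, 1, 2, 4, 6, 3, 5, 7)
              .reshape(n, c, d // fd, h // fh, w // fw, fd * fh * fw))
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        n, c, d, h, w = shape
        fd, fh, fw = self.factor
        g = np.zeros((n, c, d // fd, h // fh, w // fw, fd * fh * fw))
        np.put_along_axis(g, idx[..., None], gout[..., None], axis=-1)
        return (g.reshape(n, c, d // fd, h // fh, w // fw, fd, fh, fw)
                .transpose(0, 1, 2, 5, 3, 6, 4, 7)
                .reshape(n, c, d, h, w))


class GlobalAvgPool(Layer):
    """(N, C, D, H, W) -> (N, C); used to pool bottleneck features for heads."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._shape
        return np.broadcast_to(gout[:, :, None, None, None], self._shape) / (d * h * w)


class Linear(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["w"] = _he_init(rng, (c_in, c_out), c_in)
        self.params["b"] = np.zeros(c_out)
        self.grads["w"] = np.zeros_like(self.params["w"])
        self.grads["b"] = np.zeros(c_out)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.grads["w"] += self._x.T @ gout
        self.grads["b"] += gout.sum(axis=0)
        return gout @ self.params["w"].T


def softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adaptive-moment optimizer over a list of layers.

    Skips layers with ``trainable=False`` entirely, so freezing the encoder
    both stops its updates and removes it from optimizer state.
    """

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = list(layers)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, layer in enumerate(self.layers):
            if not layer.trainable:
                continue
            for name, p in layer.params.items():
                g = layer.grads[name]
                key = (i, name)
                m = self._m.setdefault(key, np.zeros_like(p))
                v = self._v.setdefault(key, np.zeros_like(p))
                m[...] = b1 * m + (1 - b1) * g
                v[...] = b2 * v + (1 - b2) * g * g
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
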