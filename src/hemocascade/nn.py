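"""Minimal CPU neural-network engine.

Implements exactly the layers needed by the tiny segmentation and
classification backbones: 2-D convolution (same padding, stride 1),
ReLU, 2x2 max pooling, 2x nearest-neighbour upsampling, global average
pooling and a dense layer, each with a hand-written backward pass, plus
an Adam optimizer with a cosine-annealing learning-rate schedule.

Everything runs in float32 on NumPy arrays shaped ``(N, C, H, W)``.
Parameter initialisation and any stochastic behaviour are driven by an
explicit ``numpy.random.Generator`` so that training runs are
bit-reproducible on a single thread.
"""

from __future__ import annotations

import io
from typing import Sequence

import numpy as np

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "GlobalAvgPool",
    "Linear",
    "Adam",
    "cosine_lr",
    "save_params",
    "load_params",
]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Unfold k x k same-padded patches: (N,C,H,W) -> (N*H*W, C*k*k)."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    # sliding_window_view gives (N, C, H, W, k, k) without copying
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(col)


def _col2im(col: np.ndarray, shape: tuple, k: int) -> np.ndarray:
    """Adjoint of _im2col (scatter-add of patch gradients)."""
    n, c, h, w = shape
    p = k // 2
    out = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=col.dtype)
    col6 = col.reshape(n, h, w, c, k, k)
    for di in range(k):
        for dj in range(k):
            out[:, :, di : di + h, dj : dj + w] += col6[:, :, :, :, di, dj].transpose(
                0, 3, 1, 2
            )
    if p == 0:
        return out
    return out[:, :, p : p + h, p : p + w]


class Conv2d:
    """3x3 (or 1x1) convolution, stride 1, same padding, He init."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.w = (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        col = _im2col(x, self.k)
        out = col @ self.w + self.b
        self._cache = (col, x.shape)
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        col, xshape = self._cache
        n, c, h, w = xshape
        gcol = g.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.gw = col.T @ gcol
        self.gb = gcol.sum(axis=0)
        gin = gcol @ self.w.T
        return _col2im(gin, xshape, self.k)

    @property
    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [self.gw, self.gb]


class InstanceNorm:
    """Per-sample, per-channel spatial normalization with affine params.

    Small-batch training of from-scratch conv nets is far better
    conditioned with normalization; instance norm keeps inference
    deterministic per sample (no running statistics).
    """

    def __init__(self, c: int, eps: float = 1e-5):
        self.g = np.ones(c, dtype=np.float32)
        self.b = np.zeros(c, dtype=np.float32)
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self._xhat * self.g[None, :, None, None] + self.b[None, :, None, None]

    def backward(self, gy):
        n, c, h, w = gy.shape
        m = h * w
        self.gg = (gy * self._xhat).sum(axis=(0, 2, 3))
        self.gb = gy.sum(axis=(0, 2, 3))
        gxhat = gy * self.g[None, :, None, None]
        # d/dx of (x - mu)/sqrt(var + eps) over the spatial axes
        term = (
            gxhat
            - gxhat.mean(axis=(2, 3), keepdims=True)
            - self._xhat * (gxhat * self._xhat).mean(axis=(2, 3), keepdims=True)
        )
        return term * self._inv

    @property
    def params(self):
        return [("g", self.g), ("b", self.b)]

    def grads(self):
        return [self.gg, self.gb]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask

    params: list = []

    def grads(self):
        return []


class MaxPool2:
    """2x2 max pooling, stride 2; input sides must be even."""

    def forward(self, x):
        n, c, h, w = x.shape
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = win.reshape(n, c, h // 2, w // 2, 4)
        # argmax routes gradients to the first max in a tie (deterministic)
        self._idx = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        n, c, h, w = self._shape
        gflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(gflat, self._idx[..., None], g[..., None], axis=-1)
        gr = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(gr).reshape(n, c, h, w)

    params: list = []

    def grads(self):
        return []


class Upsample2:
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x):
        self._shape = x.shape
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, g):
        n, c, h, w = self._shape
        return g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))

    params: list = []

    def grads(self):
        return []


class GlobalAvgPool:
    """(N,C,H,W) -> (N,C) spatial mean."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g):
        n, c, h, w = self._shape
        return np.broadcast_to(g[:, :, None, None], self._shape) / (h * w)

    params: list = []

    def grads(self):
        return []


class GlobalMaxPool:
    """(N,C,H,W) -> (N,C) spatial max; gradient routes to the argmax."""

    def forward(self, x):
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        self._idx = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        n, c, h, w = self._shape
        gflat = np.zeros((n, c, h * w), dtype=g.dtype)
        np.put_along_axis(gflat, self._idx[..., None], g[..., None], axis=-1)
        return gflat.reshape(self._shape)

    params: list = []

    def grads(self):
        return []


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)).astype(
            np.float32
        )
        self.b = np.zeros(d_out, dtype=np.float32)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, g):
        self.gw = self._x.T @ g
        self.gb = g.sum(axis=0)
        return g @ self.w.T

    @property
    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [self.gw, self.gb]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    """Adam with the usual (0.9, 0.999) moments and bias correction."""

    def __init__(self, layers: Sequence, lr: float = 1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [[np.zeros_like(p) for _, p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for _, p in l.params] for l in self.layers]

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for li, layer in enumerate(self.layers):
            for pi, ((_, p), g) in enumerate(zip(layer.params, layer.grads())):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def cosine_lr(lr0: float, epoch: int, total_epochs: int, lr_min: float = 0.0) -> float:
    """CosineAnnealingLR schedule value for a given epoch."""
    if total_epochs <= 1:
        return lr0
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + np.cos(np.pi * epoch / (total_epochs - 1)))


def save_params(layers: Sequence, extra: dict | None = None) -> bytes:
    """Serialize all layer parameters to an in-memory npz blob."""
    arrays = {}
    for i, layer in enumerate(layers):
        for name, p in getattr(layer, "params", []):
            arrays[f"layer{i}_{name}"] = p
    for k, v in (extra or {}).items():
        arrays[f"extra_{k}"] = np.asarray(v)
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    return buf.getvalue()


def load_params(layers: Sequence, blob: bytes) -> dict:
    """Restore parameters in place; returns any extra arrays stored."""
    with np.load(io.BytesIO(blob)) as data:
        for i, layer in enumerate(layers):
            for name, p in getattr(layer, "params", []):
                p[...] = data[f"layer{i}_{name}"]
        return {
            k[len("extra_") :]: data[k] for k in data.files if k.startswith("extra_")
        }
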