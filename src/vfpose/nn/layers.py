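"""Minimal CPU neural-network layers with explicit backward passes.

Everything operates on float32 NCHW arrays. Each layer caches what its
backward pass needs during forward; calling backward(grad) returns the
gradient with respect to the layer input and accumulates parameter
gradients into Param.grad. This is a deliberately small trainer — enough
to express MobileNetV2-style encoders and U-Net decoders and train them
deterministically on one CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _windows(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Sliding k x k windows: (N, C, Ho, Wo, k, k). Copies only via pad."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))
    if stride > 1:
        win = win[:, :, ::stride, ::stride]
    return win


def _col2im(
    gwin: np.ndarray, shape: tuple, k: int, stride: int, pad: int
) -> np.ndarray:
    """Scatter-add window gradients (N, C, k, k, Ho, Wo) back to the input."""
    n, c, h, w = shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho, wo = gwin.shape[-2:]
    gx = np.zeros((n, c, hp, wp), dtype=F32)
    for i in range(k):
        for j in range(k):
            gx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += gwin[
                :, :, i, j
            ]
    if pad:
        gx = gx[:, :, pad : pad + h, pad : pad + w]
    return gx


class Conv2d(Layer):
    """2D convolution (cross-correlation), optional bias."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        k: int = 3,
        stride: int = 1,
        pad: int | None = None,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.pad = (k // 2) if pad is None else pad
        fan_in = in_ch * k * k
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU-family nets
        self.w = Param(rng.normal(0.0, std, size=(out_ch, in_ch, k, k)))
        self.b = Param(np.zeros(out_ch)) if bias else None
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train):
        x = np.ascontiguousarray(x, dtype=F32)
        win = _windows(x, self.k, self.stride, self.pad)
        n, c, ho, wo = win.shape[0], win.shape[1], win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n, ho * wo, c * self.k * self.k
        )
        wm = self.w.value.reshape(self.out_ch, -1)
        out = cols @ wm.T  # (N, L, O)
        if self.b is not None:
            out += self.b.value
        self._cache = (cols, x.shape, ho, wo)
        return np.ascontiguousarray(out.transpose(0, 2, 1)).reshape(n, self.out_ch, ho, wo)

    def backward(self, g):
        cols, xshape, ho, wo = self._cache
        n = xshape[0]
        gl = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, self.out_ch)
        colsf = cols.reshape(n * ho * wo, -1)
        self.w.grad += (gl.T @ colsf).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += gl.sum(axis=0)
        gcols = (gl @ self.w.value.reshape(self.out_ch, -1)).reshape(
            n, ho, wo, self.in_ch, self.k, self.k
        )
        gwin = gcols.transpose(0, 3, 4, 5, 1, 2)
        self._cache = None
        return _col2im(gwin, xshape, self.k, self.stride, self.pad)


class DepthwiseConv2d(Layer):
    """Per-channel 3x3 (or k x k) convolution."""

    def __init__(
        self,
        channels: int,
        k: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        self.channels, self.k, self.stride = channels, k, stride
        self.pad = k // 2
        std = np.sqrt(2.0 / (k * k))
        self.w = Param(rng.normal(0.0, std, size=(channels, k, k)))
        self._cache = None

    def params(self):
        return [self.w]

    def forward(self, x, train):
        x = np.ascontiguousarray(x, dtype=F32)
        win = _windows(x, self.k, self.stride, self.pad)
        out = np.einsum("nchwij,cij->nchw", win, self.w.value, optimize=True)
        self._cache = (win, x.shape)
        return np.ascontiguousarray(out)

    def backward(self, g):
        win, xshape = self._cache
        self.w.grad += np.einsum("nchw,nchwij->cij", g, win, optimize=True)
        gwin = np.einsum("nchw,cij->ncijhw", g, self.w.value, optimize=True)
        self._cache = None
        return _col2im(gwin, xshape, self.k, self.stride, self.pad)


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu
            ).astype(F32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(F32)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = (x - mu[None, :, None, None]) * inv_std[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        self._cache = (xhat, inv_std, train)
        return out.astype(F32)

    def backward(self, g):
        xhat, inv_std, train = self._cache
        self.gamma.grad += np.einsum("nchw,nchw->c", g, xhat, optimize=True)
        self.beta.grad += g.sum(axis=(0, 2, 3))
        gs = g * self.gamma.value[None, :, None, None]
        if train:
            m = g.shape[0] * g.shape[2] * g.shape[3]
            mean_gs = gs.mean(axis=(0, 2, 3))
            mean_gs_xhat = np.einsum("nchw,nchw->c", gs, xhat, optimize=True) / m
            gx = inv_std[None, :, None, None] * (
                gs - mean_gs[None, :, None, None] - xhat * mean_gs_xhat[None, :, None, None]
            )
        else:
            gx = gs * inv_std[None, :, None, None]
        self._cache = None
        return gx.astype(F32)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, F32(0.0))

    def backward(self, g):
        out = np.where(self._mask, g, F32(0.0))
        self._mask = None
        return out


class Sigmoid(Layer):
    def forward(self, x, train):
        out = 1.0 / (1.0 + np.exp(-x, dtype=F32))
        self._out = out.astype(F32)
        return self._out

    def backward(self, g):
        out = g * self._out * (1.0 - self._out)
        self._out = None
        return out.astype(F32)


class Upsample2x(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x, train):
        self._shape = x.shape
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, g):
        n, c, h, w = self._shape
        return g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)).astype(F32)


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g):
        n, c, h, w = self._shape
        return (
            np.broadcast_to(g[:, :, None, None], self._shape) / F32(h * w)
        ).astype(F32)


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_f)
        self.w = Param(rng.normal(0.0, std, size=(out_f, in_f)))
        self.b = Param(np.zeros(out_f))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, g):
        self.w.grad += g.T @ self._x
        self.b.grad += g.sum(axis=0)
        gx = g @ self.w.value
        self._x = None
        return gx.astype(F32)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad.fill(0.0)

    def step(self):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(F32)


def get_weights(params: list[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def set_weights(params: list[Param], weights: list[np.ndarray]) -> None:
    if len(params) != len(weights):
        raise ValueError("weight list does not match parameter list")
    for p, w in zip(params, weights):
        if p.value.shape != w.shape:
            raise ValueError(f"shape mismatch {p.value.shape} vs {w.shape}")
        p.value = w.astype(F32).copy()
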