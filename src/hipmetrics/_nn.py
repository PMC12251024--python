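"""Minimal numpy neural-network primitives with explicit backpropagation.

Single-sample layers (inputs are ``(C, H, W)`` feature maps) sufficient for
the compact region-based keypoint network in :mod:`hipmetrics.detector`:
im2col convolutions with stride/dilation, ReLU, fully connected layers,
bilinear RoIAlign, and an SGD-with-momentum optimizer with decoupled-style
L2 weight decay.  Gradients are accumulated into ``Param.grad`` so that
mini-batches can be formed by summing per-sample backward passes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Param", "Conv2d", "ReLU", "Linear", "roi_align", "SGD"]


class Param:
    """A trainable tensor with an accumulated gradient and momentum buffer."""

    __slots__ = ("value", "grad", "velocity")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.velocity = np.zeros_like(self.value)


class Conv2d:
    """2-D convolution on a single (C, H, W) sample via im2col.

    He-normal weight initialization.  ``bias_init`` sets the initial bias of
    every output channel (used to start keypoint logits at the background
    prior, the standard dense-detection trick).
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 3,
        stride: int = 1,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
        bias_init: float = 0.0,
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel))
        self.weight = Param(w)
        self.bias = Param(np.full(c_out, bias_init))
        self.kernel, self.stride, self.dilation = kernel, stride, dilation
        self.pad = dilation * (kernel - 1) // 2  # 'same' padding for odd kernels
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _cols(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        c, h, w = x.shape
        k, s, d, p = self.kernel, self.stride, self.dilation, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        span = d * (k - 1) + 1
        windows = np.lib.stride_tricks.sliding_window_view(xp, (span, span), axis=(1, 2))
        windows = windows[:, ::s, ::s, ::d, ::d]  # (C, Ho, Wo, k, k)
        ho, wo = windows.shape[1], windows.shape[2]
        cols = windows.transpose(0, 3, 4, 1, 2).reshape(c * k * k, ho * wo)
        return np.ascontiguousarray(cols, dtype=np.float32), (xp.shape, ho, wo)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x.astype(np.float32, copy=False)
        cols, (xp_shape, ho, wo) = self._cols(x)
        w2d = self.weight.value.reshape(self.weight.value.shape[0], -1)
        out = w2d @ cols + self.bias.value[:, None]
        self._cache = (cols, xp_shape, x.shape, ho, wo)
        return out.reshape(-1, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xp_shape, x_shape, ho, wo = self._cache
        c_out = dout.shape[0]
        dout2d = dout.reshape(c_out, -1).astype(np.float32, copy=False)
        w2d = self.weight.value.reshape(c_out, -1)
        self.weight.grad += (dout2d @ cols.T).reshape(self.weight.value.shape)
        self.bias.grad += dout2d.sum(axis=1)
        dcols = (w2d.T @ dout2d).reshape(
            x_shape[0], self.kernel, self.kernel, ho, wo
        )
        k, s, d, p = self.kernel, self.stride, self.dilation, self.pad
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i * d : i * d + ho * s : s, j * d : j * d + wo * s : s] += dcols[:, i, j]
        if p:
            return dxp[:, p:-p, p:-p]
        return dxp


class ReLU:
    def __init__(self):
        self._mask = None

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = Param(rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_out, n_in)))
        self.bias = Param(np.zeros(n_out))
        self._x = None

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x.astype(np.float32, copy=False)
        return self.weight.value @ self._x + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = dout.astype(np.float32, copy=False)
        self.weight.grad += np.outer(dout, self._x)
        self.bias.grad += dout
        return self.weight.value.T @ dout


def roi_align(
    feat: np.ndarray,
    box: tuple[float, float, float, float],
    out_size: tuple[int, int],
    stride: float,
) -> tuple[np.ndarray, dict]:
    """Bilinearly sample ``feat`` (C, Hf, Wf) over ``box`` (image coords) on a grid.

    One sample per output cell, at the cell center, following the
    quantization-free RoIAlign construction.  Returns the pooled map
    (C, Sh, Sw) and a cache for :func:`roi_align_backward`.
    """
    c, hf, wf = feat.shape
    x0, y0, bw, bh = box
    sh, sw = out_size
    xs = (x0 + (np.arange(sw) + 0.5) * bw / sw) / stride - 0.5
    ys = (y0 + (np.arange(sh) + 0.5) * bh / sh) / stride - 0.5
    xs = np.clip(xs, 0.0, wf - 1.0 - 1e-6)
    ys = np.clip(ys, 0.0, hf - 1.0 - 1e-6)
    xi = np.floor(xs).astype(np.int64)
    yi = np.floor(ys).astype(np.int64)
    fx = (xs - xi).astype(np.float32)
    fy = (ys - yi).astype(np.float32)
    f00 = feat[:, yi[:, None], xi[None, :]]
    f01 = feat[:, yi[:, None], xi[None, :] + 1]
    f10 = feat[:, yi[:, None] + 1, xi[None, :]]
    f11 = feat[:, yi[:, None] + 1, xi[None, :] + 1]
    wy = fy[:, None]
    wx = fx[None, :]
    out = (
        f00 * (1 - wy) * (1 - wx)
        + f01 * (1 - wy) * wx
        + f10 * wy * (1 - wx)
        + f11 * wy * wx
    )
    cache = {"shape": feat.shape, "xi": xi, "yi": yi, "fx": fx, "fy": fy}
    return out.astype(np.float32), cache


def roi_align_backward(dout: np.ndarray, cache: dict) -> np.ndarray:
    """Scatter RoIAlign output gradients back onto the feature map."""
    c, hf, wf = cache["shape"]
    xi, yi, fx, fy = cache["xi"], cache["yi"], cache["fx"], cache["fy"]
    wy = fy[:, None]
    wx = fx[None, :]
    dfeat = np.zeros((c, hf, wf), dtype=np.float32)
    contribs = (
        ((1 - wy) * (1 - wx), 0, 0),
        ((1 - wy) * wx, 0, 1),
        (wy * (1 - wx), 1, 0),
        (wy * wx, 1, 1),
    )
    flat = dfeat.reshape(c, -1)
    idx_y = yi[:, None]
    idx_x = xi[None, :]
    for weight, oy, ox in contribs:
        lin = ((idx_y + oy) * wf + (idx_x + ox)).ravel()
        vals = (dout * weight).reshape(c, -1)
        np.add.at(flat, (slice(None), lin), vals)
    return dfeat


class SGD:
    """Stochastic gradient descent with momentum and L2 weight decay."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def clip_grad_norm(self, max_norm: float) -> float:
        """Scale all gradients so their global L2 norm is at most ``max_norm``."""
        total = math.sqrt(sum(float(np.sum(p.grad.astype(np.float64) ** 2)) for p in self.params))
        if total > max_norm and total > 0:
            scale = max_norm / total
            for p in self.params:
                p.grad *= scale
        return total

    def step(self) -> None:
        for p in self.params:
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            p.velocity[...] = self.momentum * p.velocity + g
            p.value -= self.lr * p.velocity
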