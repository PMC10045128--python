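"""Minimal NumPy neural-network engine for the segmentation model.

Implements exactly the layer set the network needs — 2-D convolution via
im2col, batch normalization, ReLU/sigmoid activations, 2x2/stride-2 max
pooling with argmax index records, index-driven max unpooling — each with a
hand-written reverse-mode gradient, plus a soft Dice loss and an Adam
optimizer.  Everything operates on NCHW float arrays and is fully
deterministic given a seeded ``numpy.random.Generator``; gradients are
validated against finite differences in the test suite.

Layout conventions
------------------
* feature maps: ``(batch, channels, height, width)``
* conv weights: ``(c_out, c_in * k * k)`` with the column order produced by
  :func:`im2col` (channel-major, then the k x k window row-major)
* pooling indices: per 2x2 window, the flat position ``dr * 2 + dc`` of the
  maximum (ties broken to the first position in row-major order).
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Unfold same-padded k x k patches: (B,C,H,W) -> (B, H*W, C*k*k)."""
    b, c, h, w = x.shape
    if k == 1:
        return x.reshape(b, c, h * w).transpose(0, 2, 1)
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B,C,H,W,k,k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b, h * w, c * k * k)


class Layer:
    """Base: parameterized layers keep ``params`` and matching ``grads`` dicts."""

    kind = "layer"

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padding 2-D convolution with bias (kernel 3x3 or 1x1 here)."""

    kind = "conv"

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.c_in, self.c_out, self.ksize = c_in, c_out, ksize
        fan_in = c_in * ksize * ksize
        scale = math.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.params["w"] = rng.normal(0.0, scale, (c_out, fan_in)).astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, c, h, w = x.shape
        cols = im2col(x, self.ksize)
        self._cols = cols if training else None
        out = cols @ self.params["w"].T + self.params["b"]
        return np.ascontiguousarray(out.transpose(0, 2, 1)).reshape(b, self.c_out, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, co, h, w = dout.shape
        k = self.ksize
        dout_r = dout.reshape(b, co, h * w).transpose(0, 2, 1)  # (B, HW, co)
        flat_d = dout_r.reshape(b * h * w, co)
        self.grads["w"] = flat_d.T @ self._cols.reshape(b * h * w, -1)
        self.grads["b"] = flat_d.sum(0)
        # input gradient = same-padded convolution of dout with the spatially
        # flipped, channel-transposed kernel
        wk = self.params["w"].reshape(co, self.c_in, k, k)
        wt = np.ascontiguousarray(wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                                  ).reshape(self.c_in, co * k * k)
        cols2 = im2col(dout, k)
        dx = cols2 @ wt.T
        self._cols = None
        return np.ascontiguousarray(dx.transpose(0, 2, 1)).reshape(b, self.c_in, h, w)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    kind = "bn"

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * invstd[:, None, None]
        if training:
            self._xhat, self._invstd = xhat, invstd
            self._m = x.shape[0] * x.shape[2] * x.shape[3]
        return self.params["gamma"][:, None, None] * xhat + self.params["beta"][:, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, invstd, m = self._xhat, self._invstd, self._m
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.params["gamma"][:, None, None]
        # per-channel sums, kept broadcastable over (B,C,H,W)
        sum_dxhat = dxhat.sum(axis=(0, 2, 3))[:, None, None]
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
        dx = (invstd[:, None, None] / m) * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
        self._xhat = None
        return dx


class ReLU(Layer):
    kind = "activation"

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class Sigmoid(Layer):
    kind = "activation"

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x))
        if training:
            self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._out * (1.0 - self._out)
        self._out = None
        return dx


# ---------------------------------------------------------------------------
# pooling primitives (stateless functions; index records flow explicitly)

def max_pool2x2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2/stride-2 max pooling over the last two axes, returning argmax indices.

    Ties break to the first maximum in row-major window order. Raises
    ``ValueError`` on odd spatial dimensions.
    """
    *lead, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
    xr = x.reshape(*lead, h // 2, 2, w // 2, 2)
    xr = np.moveaxis(xr, -3, -2).reshape(*lead, h // 2, w // 2, 4)
    idx = xr.argmax(-1)
    out = np.take_along_axis(xr, idx[..., None], -1)[..., 0]
    return out, idx


def max_unpool2x2(pooled: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Scatter pooled values back to their recorded 2x2 positions, zeros elsewhere."""
    if pooled.shape != idx.shape:
        raise ValueError(f"pooled {pooled.shape} and index {idx.shape} shapes differ")
    *lead, h, w = pooled.shape
    out4 = np.zeros((*pooled.shape, 4), dtype=pooled.dtype)
    np.put_along_axis(out4, idx[..., None], pooled[..., None], -1)
    out4 = out4.reshape(*lead, h, w, 2, 2)
    return np.moveaxis(out4, -2, -3).reshape(*lead, h * 2, w * 2)


def max_pool2x2_backward(dout: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Route pooled-output gradients back to the argmax positions."""
    return max_unpool2x2(dout, idx)


def max_unpool2x2_backward(dout: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Gather gradients from the scattered positions back to the pooled grid."""
    *lead, h2, w2 = dout.shape
    h, w = h2 // 2, w2 // 2
    dr = dout.reshape(*lead, h, 2, w, 2)
    dr = np.moveaxis(dr, -3, -2).reshape(*lead, h, w, 4)
    return np.take_along_axis(dr, idx[..., None], -1)[..., 0]


# ---------------------------------------------------------------------------
# loss and optimizer

def soft_dice_loss(pred: np.ndarray, target: np.ndarray,
                   eps: float = 1e-6) -> tuple[float, np.ndarray]:
    """Differentiable Dice loss 1 - (2*sum(p*g)+eps)/(sum(p)+sum(g)+eps).

    Computed jointly over all pixels of the batch. Returns the scalar loss
    and its gradient with respect to ``pred``. The smoothing constant defines
    the both-empty limit (loss 0).
    """
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = pred.astype(np.float64, copy=False)
    g = target.astype(np.float64, copy=False)
    inter = float((p * g).sum())
    denom = float(p.sum() + g.sum()) + eps
    num = 2.0 * inter + eps
    loss = 1.0 - num / denom
    grad = -(2.0 * g * denom - num) / (denom * denom)
    return loss, grad.astype(pred.dtype)


class Adam:
    """Adam over a named parameter collection (first/second moment per array)."""

    def __init__(self, lr: float = 5e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, named_params: Iterator[tuple[str, np.ndarray, np.ndarray]]) -> None:
        """Update each (key, param, grad) triple in place."""
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for key, p, g in named_params:
            m = self._m.setdefault(key, np.zeros_like(p))
            v = self._v.setdefault(key, np.zeros_like(p))
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
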