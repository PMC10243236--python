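"""Minimal CPU neural-network engine.

Implements exactly the layers needed by the feature-exposing classifiers in
:mod:`roidistill.models`: strided 2-D convolution (via im2col and BLAS
matmul), group normalization, ReLU, global average pooling, dropout and a
linear head, together with an Adam optimizer and a numerically stable
softmax cross-entropy.  Every layer caches its forward inputs and exposes an
explicit ``backward`` computing input gradients and accumulating parameter
gradients, so a training step is ``forward -> loss -> backward -> step``.

All computation is float32 numpy; determinism is inherited from numpy
(a seeded ``Generator`` drives every stochastic layer).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "GroupNorm",
    "ReLU",
    "GlobalAvgPool",
    "Dropout",
    "Flatten",
    "AvgPool2x2",
    "Linear",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "cosine_lr",
]


class Layer:
    """Base class: a differentiable module with (possibly empty) parameters."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for g in self.grads():
            g[...] = 0.0


def _im2col(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N*Ho*Wo, C*k*k) patch matrix."""
    n, c, hp, wp = xp.shape
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,Ho',Wo',k,k)
    win = win[:, :, ::stride, ::stride, :, :]
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, shape: tuple, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patch gradients back."""
    n, c, hp, wp = shape
    dxp = np.zeros(shape, dtype=dcols.dtype)
    d = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)  # (N,C,k,k,Ho,Wo)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d[:, :, i, j]
    return dxp


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = c_in * k * k
        # He initialization, appropriate for the ReLU nets built here
        self.W = (rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        if x.ndim != 4 or x.shape[1] != self.c_in:
            raise ValueError(f"Conv2d expects (N,{self.c_in},H,W), got {x.shape}")
        n = x.shape[0]
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2)) if self.pad else x
        xp = np.ascontiguousarray(xp, dtype=np.float32)
        ho = (xp.shape[2] - self.k) // self.stride + 1
        wo = (xp.shape[3] - self.k) // self.stride + 1
        cols = _im2col(xp, self.k, self.stride)
        out = cols @ self.W.T + self.b
        self._cache = (cols, xp.shape, n, ho, wo)
        return out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, gout):
        cols, xp_shape, n, ho, wo = self._cache
        g = gout.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.c_out)
        self.dW += g.T @ cols
        self.db += g.sum(axis=0)
        dcols = g @ self.W
        dxp = _col2im(dcols, xp_shape, self.k, self.stride, ho, wo)
        if self.pad:
            return dxp[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dxp


class GroupNorm(Layer):
    """Per-sample group normalization with a per-channel affine.

    Chosen over batch normalization because training runs at batch size 8:
    group statistics are computed per sample, so there are no running
    statistics to drift and train/eval behavior is identical.
    """

    def __init__(self, c: int, groups: int = 8, eps: float = 1e-5):
        if c % groups != 0:
            raise ValueError(f"channels {c} not divisible by groups {groups}")
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.groups, self.eps = groups, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, -1)
        mean = xg.mean(axis=2, keepdims=True, dtype=np.float32)
        var = xg.var(axis=2, keepdims=True, dtype=np.float32)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mean) * inv).reshape(n, c, h, w)
        self._cache = (xhat, inv, (n, c, h, w))
        return xhat * self.gamma[None, :, None, None] + self.beta[None, :, None, None]

    def backward(self, gout):
        xhat, inv, (n, c, h, w) = self._cache
        g = self.groups
        self.dgamma += np.einsum("nchw,nchw->c", gout, xhat, dtype=np.float32)
        self.dbeta += gout.sum(axis=(0, 2, 3), dtype=np.float32)
        gx = (gout * self.gamma[None, :, None, None]).reshape(n, g, -1)
        xh = xhat.reshape(n, g, -1)
        m = gx.shape[2]
        s1 = gx.sum(axis=2, keepdims=True)
        s2 = (gx * xh).sum(axis=2, keepdims=True)
        dx = (gx - (s1 + xh * s2) / m) * inv
        return dx.reshape(n, c, h, w).astype(np.float32)


class AvgPool2x2(Layer):
    """Non-overlapping 2x2 mean pooling (cheap antialiased downsampling)."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"AvgPool2x2 needs even spatial dims, got {x.shape}")
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, gout):
        n, c, h, w = self._shape
        g = np.repeat(np.repeat(gout, 2, axis=2), 2, axis=3) * 0.25
        return g.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train=False):
        out = np.maximum(x, 0.0)
        self._mask = out > 0
        return out

    def backward(self, gout):
        return gout * self._mask


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C) spatial mean."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout):
        n, c, h, w = self._shape
        return np.broadcast_to(gout[:, :, None, None] / (h * w), self._shape).astype(np.float32)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0,1), got {p}")
        self.p = p
        self.rng = rng or np.random.default_rng()
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gout):
        if self._mask is None:
            return gout
        return gout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        bound = np.sqrt(1.0 / d_in)
        self.W = rng.uniform(-bound, bound, (d_out, d_in)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, gout):
        self.dW += gout.T @ self._x
        self.db += gout.sum(axis=0)
        return gout @ self.W


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, gout):
        for l in reversed(self.layers):
            gout = l.backward(gout)
        return gout


class Adam:
    """Adam with the standard bias correction; lr may be changed between steps."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.grad_refs = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, self.grad_refs, self.m, self.v):
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for g in self.grad_refs:
            g[...] = 0.0


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean CE over the batch and its gradient w.r.t. the logits.

    Stable for logit magnitudes up to ~1e2 (max-subtracted log-sum-exp).
    """
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= logits.shape[1]:
        raise ValueError(f"label out of range for {logits.shape[1]} classes")
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    loss = float(np.mean(lse - z[np.arange(n), labels]))
    grad = softmax(logits)
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine decay from ``base_lr`` at epoch 0 to 0 at ``total_epochs``."""
    if total_epochs <= 0:
        raise ValueError("total_epochs must be positive")
    e = min(epoch, total_epochs)
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * e / total_epochs))
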