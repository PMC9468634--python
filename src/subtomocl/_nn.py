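"""Minimal 3D neural-network primitives with explicit backward passes.

Everything is plain numpy (float32): stride-1 'same' 3x3x3 convolutions via
im2col, 2x max pooling, dense layers, ReLU, softmax cross-entropy, L2
normalization, and Adam / SGD optimizers with an optional cosine learning-rate
schedule. Layers cache what their backward pass needs when ``keep=True``;
inference passes skip the caches.

All parameter updates happen in place, so the arrays returned by a model's
``parameters()`` stay live across optimizer steps and momentum copies.
"""

from __future__ import annotations

import math

import numpy as np

DTYPE = np.float32


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B, C, D, H, W) -> (B, D*H*W, C*k^3) patches for stride-1 convolution."""
    B, C, D, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    s = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp,
        (B, C, D, H, W, k, k, k),
        (s[0], s[1], s[2], s[3], s[4], s[2], s[3], s[4]),
    )
    return np.ascontiguousarray(
        win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(B, D * H * W, C * k**3)
    )


def _col2im(dcols: np.ndarray, xshape: tuple, k: int, pad: int) -> np.ndarray:
    B, C, D, H, W = xshape
    dp = dcols.reshape(B, D, H, W, C, k, k, k)
    dxp = np.zeros((B, C, D + 2 * pad, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    for a in range(k):
        for b in range(k):
            for c in range(k):
                dxp[:, :, a : a + D, b : b + H, c : c + W] += np.moveaxis(
                    dp[:, :, :, :, :, a, b, c], 4, 1
                )
    return dxp[:, :, pad : pad + D, pad : pad + H, pad : pad + W]


class Conv3d:
    """3x3x3 convolution, stride 1, 'same' zero padding, He-initialized."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k**3
        self.W = (rng.normal(size=(c_out, fan_in)) * math.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._xshape = None

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        B, C, D, H, W = x.shape
        cols = _im2col(x, self.k, self.k // 2)
        y = cols @ self.W.T + self.b
        if keep:
            self._cols, self._xshape = cols, x.shape
        return y.transpose(0, 2, 1).reshape(B, self.c_out, D, H, W)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, Co, D, H, W = dy.shape
        dyp = dy.reshape(B, Co, -1).transpose(0, 2, 1)  # (B, P, Co)
        flat_dy = dyp.reshape(-1, Co)
        flat_cols = self._cols.reshape(-1, self._cols.shape[-1])
        self.dW += flat_dy.T @ flat_cols
        self.db += flat_dy.sum(axis=0)
        dcols = dyp @ self.W
        return _col2im(dcols, self._xshape, self.k, self.k // 2)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        y = np.maximum(x, 0)
        if keep:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool3d:
    """Non-overlapping 2x2x2 max pooling (ties break to the first index)."""

    def __init__(self):
        self._idx = None
        self._xshape = None

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        B, C, D, H, W = x.shape
        if D % 2 or H % 2 or W % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got {x.shape}")
        xw = (
            x.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(B, C, D // 2, H // 2, W // 2, 8)
        )
        idx = xw.argmax(-1)
        y = np.take_along_axis(xw, idx[..., None], -1)[..., 0]
        if keep:
            self._idx, self._xshape = idx, x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, D, H, W = self._xshape
        dxw = np.zeros((B, C, D // 2, H // 2, W // 2, 8), dtype=dy.dtype)
        np.put_along_axis(dxw, self._idx[..., None], dy[..., None], -1)
        return (
            dxw.reshape(B, C, D // 2, H // 2, W // 2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(B, C, D, H, W)
        )


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = (rng.normal(size=(n_out, n_in)) * math.sqrt(2.0 / n_in)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        if keep:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW += dy.T @ self._x
        self.db += dy.sum(axis=0)
        return dy @ self.W

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


def l2_normalize(z: np.ndarray, eps: float = 1e-12):
    """Row-normalize; returns (unit rows, norms) — norms feed the backward."""
    n = np.linalg.norm(z, axis=1, keepdims=True)
    n = np.maximum(n, eps)
    return z / n, n


def l2_normalize_backward(dzn: np.ndarray, zn: np.ndarray, n: np.ndarray) -> np.ndarray:
    return (dzn - zn * (dzn * zn).sum(axis=1, keepdims=True)) / n


def softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    p = softmax(logits.astype(np.float64))
    B = logits.shape[0]
    loss = -np.log(np.maximum(p[np.arange(B), labels], 1e-300)).mean()
    d = p.copy()
    d[np.arange(B), labels] -= 1.0
    return float(loss), (d / B).astype(logits.dtype)


class Adam:
    def __init__(self, params: dict, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            g = grads[k].astype(np.float64)
            if self.wd:
                g = g + self.wd * p
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mh = self.m[k] / (1 - b1**self.t)
            vh = self.v[k] / (1 - b2**self.t)
            p -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(p.dtype)


class SGD:
    """SGD with classical momentum (velocity buffer)."""

    def __init__(self, params: dict, lr: float, weight_decay: float = 0.0,
                 momentum: float = 0.9):
        self.params = params
        self.lr, self.wd, self.momentum = lr, weight_decay, momentum
        self.v = {k: np.zeros_like(p) for k, p in params.items()}

    def step(self, grads: dict) -> None:
        for k, p in self.params.items():
            g = grads[k]
            if self.wd:
                g = g + self.wd * p
            self.v[k] = self.momentum * self.v[k] + g
            p -= (self.lr * self.v[k]).astype(p.dtype)


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine decay from base_lr at epoch 0 toward 0 at total_epochs."""
    if total_epochs <= 0:
        return base_lr
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * epoch / total_epochs))
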