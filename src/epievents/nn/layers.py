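"""Minimal NumPy layers with exact analytic gradients.

Everything the window classifier needs — same-padded 3×3 convolution, batch
normalisation, ReLU, 2×2 max pooling with floor division, global max pooling,
a gated recurrent unit, dropout, dense layers and softmax cross-entropy —
implemented in NHWC layout with explicit backward passes (verified by finite
differences in the test suite).  Convolutions use an im2col formulation so
the heavy lifting is a single matmul per layer.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2DSame",
    "BatchNorm",
    "ReLU",
    "MaxPool2x2",
    "GlobalMaxPool",
    "GRU",
    "Dropout",
    "Dense",
    "softmax",
    "softmax_cross_entropy",
]

_F32 = np.float32


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.ascontiguousarray(value, dtype=_F32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self):
        self.grad[...] = 0.0


def _im2col3(x_padded: np.ndarray) -> np.ndarray:
    """(N, H+2, W+2, C) -> (N*H*W, 9*C) patches in (u, v, c) order."""
    win = sliding_window_view(x_padded, (3, 3), axis=(1, 2))  # N,H,W,C,3,3
    n, h, w, c = win.shape[:4]
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * h * w, 9 * c
    )


class Conv2DSame:
    """3×3 cross-correlation with zero padding 1 (output side == input side)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 name: str = "conv"):
        std = np.sqrt(2.0 / (9 * c_in))
        self.W = Param(f"{name}_W", rng.normal(0, std, (3, 3, c_in, c_out)))
        self.b = Param(f"{name}_b", np.zeros(c_out))
        self.c_in, self.c_out = c_in, c_out
        self._cols = None
        self._shape = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = _im2col3(xp)
        y = cols @ self.W.value.reshape(9 * c, self.c_out) + self.b.value
        if train:
            self._cols, self._shape = cols, (n, h, w, c)
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        dy2 = dy.reshape(n * h * w, self.c_out)
        self.W.grad += (self._cols.T @ dy2).reshape(3, 3, c, self.c_out)
        self.b.grad += dy2.sum(axis=0)
        # dX = correlate(dY, W rotated 180° with in/out channels swapped)
        w_flip = self.W.value[::-1, ::-1].transpose(0, 1, 3, 2)  # 3,3,Cout,Cin
        dyp = np.pad(dy, ((0, 0), (1, 1), (1, 1), (0, 0)))
        dcols = _im2col3(dyp)
        dx = dcols @ w_flip.reshape(9 * self.c_out, c)
        self._cols = None
        return dx.reshape(n, h, w, c)


class BatchNorm:
    """Per-channel batch normalisation over (N, H, W); activation comes after."""

    def __init__(self, c: int, name: str = "bn", momentum: float = 0.9,
                 eps: float = 1e-5):
        self.gamma = Param(f"{name}_gamma", np.ones(c))
        self.beta = Param(f"{name}_beta", np.zeros(c))
        self.running_mean = np.zeros(c, dtype=_F32)
        self.running_var = np.ones(c, dtype=_F32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(_F32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(_F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._cache = (xhat, inv_std, axes, x.shape)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, shape = self._cache
        m = np.prod([shape[a] for a in axes])
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.value
        dx = (
            dxhat
            - dxhat.mean(axis=axes)
            - xhat * (dxhat * xhat).mean(axis=axes)
        ) * inv_std
        self._cache = None
        return dx


class ReLU:
    params: list = []

    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2x2:
    """2×2 max pooling, stride 2; odd trailing rows/columns are dropped
    (floor division of the spatial side: 45 → 22 → 11 → 5)."""

    params: list = []

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        xc = x[:, : 2 * ho, : 2 * wo, :]
        win = xc.reshape(n, ho, 2, wo, 2, c).transpose(0, 1, 3, 5, 2, 4)
        win = win.reshape(n, ho, wo, c, 4)
        idx = win.argmax(axis=-1)
        y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (n, h, w, c) = self._cache
        ho, wo = h // 2, w // 2
        dwin = np.zeros((n, ho, wo, c, 4), dtype=dy.dtype)
        np.put_along_axis(dwin, idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros((n, h, w, c), dtype=dy.dtype)
        dx[:, : 2 * ho, : 2 * wo, :] = (
            dwin.reshape(n, ho, wo, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, 2 * ho, 2 * wo, c)
        )
        self._cache = None
        return dx


class GlobalMaxPool:
    """Collapse the remaining spatial grid to one feature vector per image."""

    params: list = []

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        flat = x.reshape(n, h * w, c)
        idx = flat.argmax(axis=1)
        y = np.take_along_axis(flat, idx[:, None, :], axis=1)[:, 0, :]
        if train:
            self._cache = (idx, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (n, h, w, c) = self._cache
        dflat = np.zeros((n, h * w, c), dtype=dy.dtype)
        np.put_along_axis(dflat, idx[:, None, :], dy[:, None, :], axis=1)
        self._cache = None
        return dflat.reshape(n, h, w, c)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class GRU:
    """Gated recurrent unit over a (B, T, D) sequence; returns the last state.

    Gate order in the fused weight matrices is (update z, reset r,
    candidate h̃), with ``h_t = z·h_{t-1} + (1-z)·h̃``.
    """

    def __init__(self, d_in: int, units: int, rng: np.random.Generator,
                 name: str = "gru"):
        lim_x = np.sqrt(6.0 / (d_in + units))
        lim_h = np.sqrt(6.0 / (units + units))
        self.Wx = Param(f"{name}_Wx", rng.uniform(-lim_x, lim_x, (d_in, 3 * units)))
        self.Wh = Param(f"{name}_Wh", rng.uniform(-lim_h, lim_h, (units, 3 * units)))
        self.b = Param(f"{name}_b", np.zeros(3 * units))
        self.units = units
        self.d_in = d_in
        self._cache = None

    @property
    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, t, d = x.shape
        u = self.units
        h = np.zeros((b, u), dtype=_F32)
        steps = []
        for k in range(t):
            xt = x[:, k, :]
            gx = xt @ self.Wx.value + self.b.value
            gh = h @ self.Wh.value
            z = _sigmoid(gx[:, :u] + gh[:, :u])
            r = _sigmoid(gx[:, u : 2 * u] + gh[:, u : 2 * u])
            gh_c = gh[:, 2 * u :]
            cand = np.tanh(gx[:, 2 * u :] + r * gh_c)
            h_new = z * h + (1 - z) * cand
            if train:
                steps.append((xt, h, z, r, cand, gh_c))
            h = h_new
        if train:
            self._cache = (steps, x.shape)
        return h

    def backward(self, dh: np.ndarray) -> np.ndarray:
        steps, (b, t, d) = self._cache
        u = self.units
        dx = np.zeros((b, t, d), dtype=_F32)
        dh = dh.astype(_F32, copy=True)
        for k in range(t - 1, -1, -1):
            xt, h_prev, z, r, cand, gh_c = steps[k]
            dz = dh * (h_prev - cand)
            dcand = dh * (1 - z)
            dh_prev = dh * z
            da_c = dcand * (1 - cand * cand)
            dr = da_c * gh_c
            dgh_c = da_c * r
            da_z = dz * z * (1 - z)
            da_r = dr * r * (1 - r)
            dgx = np.concatenate([da_z, da_r, da_c], axis=1)
            dgh = np.concatenate([da_z, da_r, dgh_c], axis=1)
            self.Wx.grad += xt.T @ dgx
            self.Wh.grad += h_prev.T @ dgh
            self.b.grad += dgx.sum(axis=0)
            dx[:, k, :] = dgx @ self.Wx.value.T
            dh = dh_prev + dgh @ self.Wh.value.T
        self._cache = None
        return dx


class Dropout:
    params: list = []

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x: np.ndarray, train: bool,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        rng = np.random.default_rng() if rng is None else rng
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 name: str = "dense"):
        std = np.sqrt(2.0 / d_in)
        self.W = Param(f"{name}_W", rng.normal(0, std, (d_in, d_out)))
        self.b = Param(f"{name}_b", np.zeros(d_out))
        self._x = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.W.value.T
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean categorical cross-entropy; returns (loss, dlogits, probs).

    ``labels`` are integer class indices.
    """
    probs = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return float(loss), dlogits.astype(_F32), probs


class Adam:
    """Adam optimiser over a parameter list."""

    def __init__(self, params: list, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
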