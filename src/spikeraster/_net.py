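"""Minimal numpy neural-network layers used by the CNN classifier.

Forward/backward passes are vectorized over the batch: convolutions go
through im2col + one BLAS matmul, max-pooling uses strided window views
with argmax scatter for the gradient.  All tensors are float32 NCHW.
Each layer owns its parameters and gradients; the RMSprop optimizer
walks the layer list.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Layer:
    """Base: stateless by default; trainable layers override params()."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """2D convolution (cross-correlation), He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None) -> None:
        if kernel < 1 or stride < 1 or pad < 0:
            raise ValueError("invalid convolution geometry")
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.weight = rng.normal(0.0, scale, (out_ch, in_ch * kernel * kernel)).astype(F32)
        self.bias = np.zeros(out_ch, dtype=F32)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self._cols: np.ndarray | None = None
        self._x_shape: tuple | None = None

    def params(self):
        return {"weight": self.weight, "bias": self.bias}

    def grads(self):
        return {"weight": self.dweight, "bias": self.dbias}

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.kernel, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo = win.shape[:4]
        # (N, Ho, Wo, C*k*k)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, ho * wo, c * k * k)

    def forward(self, x, train):
        n, _, h, w = x.shape
        ho, wo = self.out_hw(h, w)
        cols = self._im2col(x)
        out = cols @ self.weight.T + self.bias
        if train:
            self._cols, self._x_shape = cols, x.shape
        return out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, f, ho, wo = dy.shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(n, ho * wo, f)
        self.dweight[:] = np.einsum("npf,npc->fc", dyf, self._cols, optimize=True)
        self.dbias[:] = dyf.sum(axis=(0, 1))
        dcols = dyf @ self.weight  # (N, Ho*Wo, C*k*k)
        k, s, p = self.kernel, self.stride, self.pad
        _, c, h, w = self._x_shape
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        dcols = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        for a in range(k):
            for b in range(k):
                dxp[:, :, a:a + ho * s:s, b:b + wo * s:s] += dcols[:, :, :, :, a, b]
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ReLU(Layer):
    def forward(self, x, train):
        if train:
            self._mask = x > 0
        else:
            return np.maximum(x, 0)
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2D(Layer):
    """Max pooling; output size floor((N-K)/S)+1 per axis (excess cropped)."""

    def __init__(self, kernel: int = 2, stride: int = 2) -> None:
        if kernel < 1 or stride < 1:
            raise ValueError("invalid pooling geometry")
        self.kernel, self.stride = kernel, stride

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        k, s = self.kernel, self.stride
        if h < k or w < k:
            raise ValueError("pooling input smaller than kernel")
        return (h - k) // s + 1, (w - k) // s + 1

    def forward(self, x, train):
        k, s = self.kernel, self.stride
        ho, wo = self.out_hw(x.shape[2], x.shape[3])
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(*win.shape[:4], k * k)
        if train:
            self._arg = flat.argmax(axis=-1)
            self._x_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dy):
        k, s = self.kernel, self.stride
        n, c, ho, wo = dy.shape
        dx = np.zeros(self._x_shape, dtype=F32)
        a, b = np.unravel_index(self._arg, (k, k))
        ni, ci, hi, wi = np.indices((n, c, ho, wo), sparse=True)
        np.add.at(dx, (ni, ci, hi * s + a, wi * s + b), dy)
        return dx


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        self.gamma = np.ones(channels, dtype=F32)
        self.beta = np.zeros(channels, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def forward(self, x, train):
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
            self._xhat, self._inv = xhat, inv
            return g * xhat + b
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return g * ((x - self.running_mean.reshape(1, -1, 1, 1))
                    * inv.reshape(1, -1, 1, 1)) + b

    def backward(self, dy):
        xhat, inv = self._xhat, self._inv
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.dgamma[:] = (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta[:] = dy.sum(axis=(0, 2, 3))
        g = self.gamma.reshape(1, -1, 1, 1)
        dxhat = dy * g
        term = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m)
        return term * inv.reshape(1, -1, 1, 1)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_dim)
        self.weight = rng.normal(0.0, scale, (in_dim, out_dim)).astype(F32)
        self.bias = np.zeros(out_dim, dtype=F32)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)

    def params(self):
        return {"weight": self.weight, "bias": self.bias}

    def grads(self):
        return {"weight": self.dweight, "bias": self.dbias}

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.weight + self.bias

    def backward(self, dy):
        self.dweight[:] = self._x.T @ dy
        self.dbias[:] = dy.sum(axis=0)
        return dy @ self.weight.T


class Dropout(Layer):
    """Inverted dropout; identity at prediction time."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy):
        if self.rate == 0.0:
            return dy
        return dy * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray):
    """Returns (loss, probs, dlogits) for mean categorical cross-entropy."""
    probs = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-(onehot * np.log(probs + 1e-12)).sum() / n)
    dlogits = ((probs - onehot) / n).astype(F32)
    return loss, probs, dlogits


class RMSprop:
    """Keep a running mean of squared gradients; divide steps by its root."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 rho: float = 0.9, eps: float = 1e-8) -> None:
        self.layers = [ly for ly in layers if ly.params()]
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache = [
            {k: np.zeros_like(v) for k, v in ly.params().items()} for ly in self.layers
        ]

    def step(self) -> None:
        for ly, cache in zip(self.layers, self.cache):
            ps, gs = ly.params(), ly.grads()
            for k in ps:
                c = cache[k]
                g = gs[k]
                c *= self.rho
                c += (1.0 - self.rho) * g * g
                ps[k] -= self.lr * g / (np.sqrt(c) + self.eps)
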