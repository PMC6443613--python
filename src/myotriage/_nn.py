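"""Minimal deterministic neural-network layers on numpy.

Implements exactly what the two trainable image models need: 2D
convolution (im2col), max-pooling, nearest-neighbour upsampling, dense
layers, ReLU, and an Adam optimizer.  Everything is float64 and driven
by an explicit ``numpy.random.Generator``, so a fixed seed reproduces
training bit-for-bit on any platform.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "Dense",
    "Flatten",
    "MaxPool2D",
    "ReLU",
    "Reshape",
    "Sequential",
    "Upsample2D",
    "Adam",
    "bce_with_logits",
    "mse_loss",
]


class Layer:
    """Base class: stateless layers override forward/backward only."""

    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2D(Layer):
    """2D convolution (cross-correlation) over (N, C, H, W) batches.

    padding="valid" shrinks the map by k-1; padding="same" zero-pads so
    the output grid equals the input grid (stride is always 1).
    """

    def __init__(self, in_channels, out_channels, kernel_size, rng, padding="valid"):
        super().__init__()
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        self.k = int(kernel_size)
        self.padding = padding
        fan_in = in_channels * self.k * self.k
        self.W = _he_init(rng, (out_channels, in_channels, self.k, self.k), fan_in)
        self.b = np.zeros(out_channels)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]
        self._cols = None
        self._xshape = None

    def _pad(self):
        return (self.k - 1) // 2 if self.padding == "same" else 0

    def forward(self, x):
        n, c, h, w = x.shape
        p = self._pad()
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, -1)
        self._cols = cols
        self._xshape = (n, c, h, w, ho, wo)
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, c, h, w, ho, wo = self._xshape
        f = self.W.shape[0]
        gmat = grad.transpose(0, 2, 3, 1).reshape(-1, f)
        self.dW[...] = (gmat.T @ self._cols).reshape(self.W.shape)
        self.db[...] = gmat.sum(axis=0)
        dcols = (gmat @ self.W.reshape(f, -1)).reshape(n, ho, wo, c, self.k, self.k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (n, c, ho, wo, k, k)
        p = self._pad()
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + ho, j : j + wo] += dcols[:, :, :, :, i, j]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class MaxPool2D(Layer):
    def __init__(self, size=2):
        super().__init__()
        self.size = int(size)

    def forward(self, x):
        n, c, h, w = x.shape
        s = self.size
        ho, wo = h // s, w // s
        xc = x[:, :, : ho * s, : wo * s]
        win = xc.reshape(n, c, ho, s, wo, s).transpose(0, 1, 2, 4, 3, 5)
        flat = win.reshape(n, c, ho, wo, s * s)
        self._arg = flat.argmax(axis=-1)
        self._xshape = (n, c, h, w)
        return flat.max(axis=-1)

    def backward(self, grad):
        n, c, h, w = self._xshape
        s = self.size
        ho, wo = grad.shape[2], grad.shape[3]
        dflat = np.zeros((n, c, ho, wo, s * s))
        np.put_along_axis(dflat, self._arg[..., None], grad[..., None], axis=-1)
        dwin = dflat.reshape(n, c, ho, wo, s, s).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((n, c, h, w))
        dx[:, :, : ho * s, : wo * s] = dwin.reshape(n, c, ho * s, wo * s)
        return dx


class Upsample2D(Layer):
    """Nearest-neighbour upsampling by an integer factor."""

    def __init__(self, factor=2):
        super().__init__()
        self.f = int(factor)

    def forward(self, x):
        return x.repeat(self.f, axis=2).repeat(self.f, axis=3)

    def backward(self, grad):
        n, c, h, w = grad.shape
        f = self.f
        return grad.reshape(n, c, h // f, f, w // f, f).sum(axis=(3, 5))


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        super().__init__()
        self.shape = tuple(shape)

    def forward(self, x):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in)


class Dense(Layer):
    def __init__(self, in_features, out_features, rng):
        super().__init__()
        self.W = _he_init(rng, (in_features, out_features), in_features)
        self.b = np.zeros(out_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class Sequential(Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)
        for lay in self.layers:
            self.params.extend(lay.params)
            self.grads.extend(lay.grads)

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, grad):
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return grad


class Adam:
    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.grads = grads
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_with_logits(z, y):
    """Mean binary cross-entropy on logits; returns (loss, dL/dz)."""
    z = z.ravel()
    y = np.asarray(y, dtype=float).ravel()
    # log(1 + e^z) computed stably
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    p = 1.0 / (1.0 + np.exp(-z))
    return loss, ((p - y) / z.size).reshape(-1, 1)


def mse_loss(x, target):
    """Mean squared error; returns (loss, dL/dx)."""
    diff = x - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size
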