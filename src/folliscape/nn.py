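"""Minimal NumPy convolutional-network engine.

The detection and classification networks used in this package are
deliberately tiny (well under 200k parameters) so that they train on a
single CPU in seconds to minutes. At that scale a small, fully inspectable
NumPy implementation (im2col convolutions, hand-written backprop, Adam)
keeps the package self-contained and bit-reproducible under a fixed seed.

Conventions: activations are float64 arrays shaped (N, C, H, W) for
convolutional layers and (N, D) for dense layers. Convolutions are stride-1
with "same" zero padding and odd kernel sizes.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2x2",
    "Upsample2x",
    "Flatten",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "softplus",
]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softplus(z):
    return np.logaddexp(0.0, z)


class Layer:
    """Base layer: forward caches what backward needs; params/grads exposed."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self):
        return []

    def gradients(self):
        return []


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        # He initialisation
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.k = k
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._win = None

    def forward(self, x):
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
        self._win = win
        return np.einsum("nchwij,ocij->nohw", win, self.W, optimize=True) + self.b[None, :, None, None]

    def backward(self, g):
        k, p = self.k, self.k // 2
        self.dW[...] = np.einsum("nohw,nchwij->ocij", g, self._win, optimize=True)
        self.db[...] = g.sum(axis=(0, 2, 3))
        gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p)))
        gwin = sliding_window_view(gp, (k, k), axis=(2, 3))
        Wf = self.W[:, :, ::-1, ::-1]
        return np.einsum("nohwij,ocij->nchw", gwin, Wf, optimize=True)

    def parameters(self):
        return [self.W, self.b]

    def gradients(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g):
        return g * self._mask


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)


class MaxPool2x2(Layer):
    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(out, self._idx[..., None], g[..., None], axis=-1)
        return out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, g):
        n, c, h, w = g.shape
        return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g):
        n, c, h, w = self._shape
        return np.broadcast_to(g[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.W.T

    def parameters(self):
        return [self.W, self.b]

    def gradients(self):
        return [self.dW, self.db]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def gradients(self):
        return [g for layer in self.layers for g in layer.gradients()]


class Adam:
    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
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


def state_dict(model: Sequential) -> list[np.ndarray]:
    return [p.copy() for p in model.parameters()]


def load_state(model: Sequential, state: list[np.ndarray]) -> None:
    for p, s in zip(model.parameters(), state):
        p[...] = s
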