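"""Compact NumPy neural-network layer stack with manual backpropagation.

Provides the small trainable architectures used by the audit models: dense
layers, ReLU, 2-D convolution (im2col), average pooling, and an Adam
optimizer.  Everything is deterministic given a ``numpy.random.Generator``.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = [
    "Dense",
    "ReLU",
    "Conv2d",
    "AvgPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Sequential",
    "Adam",
    "bce_with_logits",
    "softmax_cross_entropy",
    "params_checksum",
]


class Layer:
    """Base class: stateless unless it owns parameters."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He-style scaling; works for both ReLU and linear heads at this size
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(
            np.float64
        )
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """x: (n, c, h, w) -> columns (n, out_h, out_w, c*k*k)."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out_h = (x.shape[2] - k) // stride + 1
    out_w = (x.shape[3] - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, out_h, out_w, k, k),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
        writeable=False,
    )
    # (n, out_h, out_w, c, k, k)
    cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n, out_h, out_w, c * k * k)
    return cols, out_h, out_w


class Conv2d(Layer):
    """2-D convolution via im2col; input layout (n, c, h, w)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int = 0,
        bias: bool = True,
    ):
        fan_in = c_in * k * k
        self.W = (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(
            np.float64
        )
        self.b = np.zeros(c_out) if bias else None
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None

    def forward(self, x):
        self._xshape = x.shape
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        self._cols = cols
        out = cols @ self.W
        if self.b is not None:
            out = out + self.b
        # (n, oh, ow, c_out) -> (n, c_out, oh, ow)
        return out.transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, c_out, oh, ow = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(-1, c_out)
        cols = self._cols.reshape(-1, self.W.shape[0])
        self.dW[...] = cols.T @ g
        if self.b is not None:
            self.db[...] = g.sum(axis=0)
        dcols = (g @ self.W.T).reshape(n, oh, ow, self.c_in, self.k, self.k)
        # scatter-add back into padded input
        _, c, h, w = self._xshape
        hp, wp = h + 2 * self.pad, w + 2 * self.pad
        dx = np.zeros((n, c, hp, wp))
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dx[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        if self.pad:
            dx = dx[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dx

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def grads(self):
        return [self.dW] + ([self.db] if self.db is not None else [])


class AvgPool2d(Layer):
    """Non-overlapping average pooling; spatial dims must divide by k."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x):
        n, c, h, w = x.shape
        k = self.k
        self._shape = x.shape
        return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(self, grad):
        n, c, h, w = self._shape
        k = self.k
        g = grad[:, :, :, None, :, None] / (k * k)
        return np.broadcast_to(g, (n, c, h // k, k, w // k, k)).reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), self._shape).copy()


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]


class Adam:
    def __init__(self, params: list[np.ndarray], lr=1e-2, beta1=0.9, beta2=0.999,
                 eps=1e-8, weight_decay=0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if self.weight_decay:
                g = g + self.weight_decay * p
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy over all elements; returns (loss, dlogits)."""
    z, y = logits, targets
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    p = 1.0 / (1.0 + np.exp(-z))
    return loss, (p - y) / z.size


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """labels: integer class indices; returns (loss, dlogits)."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-300))
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return loss, d / n


def params_checksum(params: list[np.ndarray]) -> str:
    """SHA-256 over the concatenated parameter bytes (bitwise freeze check)."""
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p).tobytes())
    return h.hexdigest()
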