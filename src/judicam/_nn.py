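"""Minimal numpy neural-network engine used by the classifier and autoencoders.

Layers operate on float64 batches shaped (N, C, H, W). Every layer exposes

    forward(x) -> (y, cache)
    backward(dy, cache) -> (dx, grads)

where ``grads`` aligns with ``layer.params``. Forward passes are pure
functions of the input and the current parameters, which keeps training and
activation/gradient extraction bit-deterministic on a single thread.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3x3",
    "ReLU",
    "LeakyReLU",
    "MaxPool2",
    "AvgPool2",
    "Upsample2",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "Adam",
    "SGD",
    "softmax",
]


def _im2col3(x: np.ndarray) -> np.ndarray:
    """Unfold 3x3 neighbourhoods (zero padding 1) into columns.

    (N, C, H, W) -> (N, C*9, H*W)
    """
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((n, c, 9, h, w), dtype=x.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[:, :, k] = xp[:, :, di : di + h, dj : dj + w]
            k += 1
    return cols.reshape(n, c * 9, h * w)


def _col2im3(cols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col3` (scatter-add back to image layout)."""
    n, c, h, w = shape
    cols = cols.reshape(n, c, 9, h, w)
    out = np.zeros((n, c, h + 2, w + 2), dtype=cols.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            out[:, :, di : di + h, dj : dj + w] += cols[:, :, k]
            k += 1
    return out[:, :, 1:-1, 1:-1]


class Layer:
    params: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy, cache):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero padding 1 (shape preserving)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * 9))  # He initialisation for ReLU nets
        self.w = rng.normal(0.0, scale, size=(c_out, c_in * 9))
        self.b = np.zeros(c_out)
        self.c_in, self.c_out = c_in, c_out
        self.params = [self.w, self.b]

    def forward(self, x):
        n, c, h, w = x.shape
        cols = _im2col3(x)  # (n, k, p)
        k = cols.shape[1]
        flat = cols.transpose(1, 0, 2).reshape(k, n * h * w)
        y = (self.w @ flat).reshape(self.c_out, n, h * w).transpose(1, 0, 2)
        y = y + self.b[None, :, None]
        return y.reshape(n, self.c_out, h, w), (flat, x.shape)

    def backward(self, dy, cache):
        flat, xshape = cache
        n, _, h, w = xshape
        dyf = dy.reshape(n, self.c_out, h * w).transpose(1, 0, 2).reshape(self.c_out, n * h * w)
        dw = dyf @ flat.T
        db = dyf.sum(axis=1)
        dflat = self.w.T @ dyf  # (k, n*p)
        dcols = dflat.reshape(self.c_in * 9, n, h * w).transpose(1, 0, 2)
        dx = _col2im3(dcols, (n, self.c_in, h, w))
        return dx, [dw, db]


class ReLU(Layer):
    def forward(self, x):
        y = np.maximum(x, 0.0)
        return y, (x > 0.0)

    def backward(self, dy, cache):
        return dy * cache, []


class LeakyReLU(Layer):
    """Leaky rectifier; avoids dead units in small regression decoders."""

    def __init__(self, slope: float = 0.1):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        pos = x > 0.0
        return np.where(pos, x, self.slope * x), pos

    def backward(self, dy, cache):
        return np.where(cache, dy, self.slope * dy), []


class MaxPool2(Layer):
    """2x2 max pooling, stride 2. Requires even spatial dims."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        mask = xr == y[:, :, :, None, :, None]
        # break 2x2 ties deterministically: keep only the first max position
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        mask = (flat & first).reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return y, (mask, x.shape)

    def backward(self, dy, cache):
        mask, xshape = cache
        n, c, h, w = xshape
        dx = mask * dy[:, :, :, None, :, None]
        return dx.reshape(n, c, h, w), []


class AvgPool2(Layer):
    """2x2 average pooling, stride 2."""

    def forward(self, x):
        n, c, h, w = x.shape
        y = x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
        return y, x.shape

    def backward(self, dy, cache):
        n, c, h, w = cache
        dx = np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) / 4.0
        return dx, []


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling (resize-conv decoders)."""

    def forward(self, x):
        y = np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)
        return y, x.shape

    def backward(self, dy, cache):
        n, c, h, w = cache
        dx = dy.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
        return dx, []


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x):
        return x.mean(axis=(2, 3)), x.shape

    def backward(self, dy, cache):
        n, c, h, w = cache
        dx = np.broadcast_to(dy[:, :, None, None], (n, c, h, w)) / (h * w)
        return dx.copy(), []


class Linear(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(1.0 / c_in)
        self.w = rng.normal(0.0, scale, size=(c_out, c_in))
        self.b = np.zeros(c_out)
        self.params = [self.w, self.b]

    def forward(self, x):
        return x @ self.w.T + self.b, x

    def backward(self, dy, cache):
        dw = dy.T @ cache
        db = dy.sum(axis=0)
        dx = dy @ self.w
        return dx, [dw, db]


class Sequential:
    """Ordered layer stack with tap access for intermediate activations."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def set_params(self, values: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for j in range(len(layer.params)):
                layer.params[j][...] = values[i]
                i += 1
        # rebind convenience attributes
        for layer in self.layers:
            if isinstance(layer, (Conv3x3, Linear)):
                layer.w, layer.b = layer.params

    def forward(self, x, start: int = 0, stop: int | None = None):
        """Run layers [start, stop); returns output and per-layer caches."""
        caches = []
        for layer in self.layers[start:stop]:
            x, cache = layer.forward(x)
            caches.append(cache)
        return x, caches

    def backward(self, dy, caches, start: int = 0, stop: int | None = None):
        """Backprop through layers [start, stop) given their caches."""
        grads: list[list[np.ndarray]] = []
        layers = self.layers[start:stop]
        for layer, cache in zip(reversed(layers), reversed(caches)):
            dy, g = layer.backward(dy, cache)
            grads.append(g)
        grads.reverse()
        return dy, [g for gs in grads for g in gs]


class SGD:
    def __init__(self, params: list[np.ndarray], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, v in zip(self.params, grads, self.v):
            v *= self.momentum
            v += g
            p -= self.lr * v


class Adam:
    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
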