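"""Minimal CPU layers for the small convolutional classifiers.

Each layer exposes ``forward(x, training, rng)`` and ``backward(grad)``;
parameters and their gradients live in the ``params`` / ``grads`` dicts so
optimizers can update them uniformly.  A frozen layer (``trainable=False``)
still propagates gradients to earlier layers but is skipped by the
optimizer.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "Conv2D", "ReLU", "MaxPool2", "GlobalAvgPool", "Dense", "Dropout"]


class Layer:
    trainable = True

    def __init__(self):
        self.params: dict = {}
        self.grads: dict = {}

    def forward(self, x, training=False, rng=None):  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.params.values())


class Conv2D(Layer):
    """3x3 same-padding convolution, stride 1, NHWC layout."""

    def __init__(self, in_channels: int, filters: int, rng: np.random.Generator):
        super().__init__()
        fan_in = 9 * in_channels
        scale = np.sqrt(2.0 / fan_in)  # He init for the ReLU that follows
        self.params = {
            "W": rng.standard_normal((3, 3, in_channels, filters)) * scale,
            "b": np.zeros(filters),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, training=False, rng=None):
        self._xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        W, b = self.params["W"], self.params["b"]
        n, h, w, _ = x.shape
        out = np.broadcast_to(b, (n, h, w, b.shape[0])).copy()
        for di in range(3):
            for dj in range(3):
                out += np.tensordot(
                    self._xp[:, di : di + h, dj : dj + w, :], W[di, dj], axes=([3], [0])
                )
        return out

    def backward(self, grad):
        W = self.params["W"]
        n, h, w, _ = grad.shape
        dxp = np.zeros_like(self._xp)
        dW = np.zeros_like(W)
        for di in range(3):
            for dj in range(3):
                patch = self._xp[:, di : di + h, dj : dj + w, :]
                dW[di, dj] = np.tensordot(patch, grad, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, di : di + h, dj : dj + w, :] += np.tensordot(
                    grad, W[di, dj], axes=([3], [1])
                )
        self.grads["W"] = dW
        self.grads["b"] = grad.sum(axis=(0, 1, 2))
        return dxp[:, 1:-1, 1:-1, :]


class ReLU(Layer):
    trainable = False

    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    trainable = False

    def forward(self, x, training=False, rng=None):
        n, h, w, c = x.shape
        if h < 2 or w < 2:  # nothing left to pool
            self._passthrough = True
            return x
        self._passthrough = False
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xr = x[:, : h2 * 2, : w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
        self._xr = xr
        out = xr.max(axis=(2, 4))
        self._out = out
        return out

    def backward(self, grad):
        if self._passthrough:
            return grad
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        mask = self._xr == self._out[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)  # split ties evenly
        dxr = mask * (grad[:, :, None, :, None, :] / counts)
        dx = np.zeros(self._in_shape)
        dx[:, : h2 * 2, : w2 * 2, :] = dxr.reshape(n, h2 * 2, w2 * 2, c)
        return dx


class GlobalAvgPool(Layer):
    trainable = False

    def forward(self, x, training=False, rng=None):
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._in_shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w), self._in_shape).copy()


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(1.0 / in_features)
        self.params = {
            "W": rng.standard_normal((in_features, out_features)) * scale,
            "b": np.zeros(out_features),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity outside training or at rate 0."""

    trainable = False

    def __init__(self, rate: float):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.uniform(size=x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask
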