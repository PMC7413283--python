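"""Minimal 1-D convolutional network primitives with manual backpropagation.

Implements exactly what the autoencoder needs — valid convolution, transposed
convolution, batch normalization, tanh and clamped-tanh activations, and an
Adam optimizer — in numpy (float32, im2col + BLAS matmul).  Shapes follow
the (batch, channels, length) convention.

Every layer caches what its backward pass needs during forward(); calling
backward() returns the gradient with respect to the layer input and stores
parameter gradients in ``layer.grads``.
"""

from __future__ import annotations

import math

import numpy as np

DTYPE = np.float32


class Layer:
    """Base class: parameter-free layers leave params/grads empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Conv1d(Layer):
    """Valid (no-padding) strided 1-D convolution."""

    def __init__(self, in_channels: int, out_channels: int, filter_size: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout, self.f, self.s = in_channels, out_channels, filter_size, stride
        fan = in_channels * filter_size
        self.params["W"] = _glorot(rng, (out_channels, in_channels, filter_size), fan, out_channels * filter_size)
        self.params["b"] = np.zeros(out_channels, dtype=DTYPE)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[1] != self.cin:
            raise ValueError("channel mismatch")
        b, _, length = x.shape
        lout = (length - self.f) // self.s + 1
        if lout < 1:
            raise ValueError("input shorter than filter")
        win = np.lib.stride_tricks.sliding_window_view(x, self.f, axis=2)[:, :, :: self.s, :]
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(b * lout, self.cin * self.f)
        w = self.params["W"].reshape(self.cout, -1)
        y = cols @ w.T + self.params["b"]
        self._cache = (cols, x.shape, lout)
        return np.ascontiguousarray(y.reshape(b, lout, self.cout).transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, lout = self._cache
        b = x_shape[0]
        dym = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(b * lout, self.cout)
        self.grads["W"] = (dym.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"] = dym.sum(axis=0)
        dcols = (dym @ self.params["W"].reshape(self.cout, -1)).reshape(b, lout, self.cin, self.f)
        dx = np.zeros(x_shape, dtype=DTYPE)
        for j in range(self.f):
            dx[:, :, j : j + self.s * lout : self.s] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dx


class ConvTranspose1d(Layer):
    """Transposed 1-D convolution; output length (L - 1) * s + f."""

    def __init__(self, in_channels: int, out_channels: int, filter_size: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout, self.f, self.s = in_channels, out_channels, filter_size, stride
        fan = in_channels * filter_size
        self.params["W"] = _glorot(rng, (in_channels, out_channels, filter_size), fan, out_channels * filter_size)
        self.params["b"] = np.zeros(out_channels, dtype=DTYPE)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[1] != self.cin:
            raise ValueError("channel mismatch")
        b, _, length = x.shape
        lout = (length - 1) * self.s + self.f
        xt = np.ascontiguousarray(x.transpose(0, 2, 1)).reshape(b * length, self.cin)
        contrib = (xt @ self.params["W"].reshape(self.cin, -1)).reshape(b, length, self.cout, self.f)
        y = np.zeros((b, self.cout, lout), dtype=DTYPE)
        for j in range(self.f):
            y[:, :, j : j + self.s * length : self.s] += contrib[:, :, :, j].transpose(0, 2, 1)
        y += self.params["b"][None, :, None]
        self._cache = (xt, x.shape, length)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xt, x_shape, length = self._cache
        b = x_shape[0]
        dcontrib = np.empty((b, length, self.cout, self.f), dtype=DTYPE)
        for j in range(self.f):
            dcontrib[:, :, :, j] = dy[:, :, j : j + self.s * length : self.s].transpose(0, 2, 1)
        dflat = dcontrib.reshape(b * length, self.cout * self.f)
        self.grads["W"] = (xt.T @ dflat).reshape(self.params["W"].shape)
        self.grads["b"] = dy.sum(axis=(0, 2))
        dx = dflat @ self.params["W"].reshape(self.cin, -1).T
        return np.ascontiguousarray(dx.reshape(b, length, self.cin).transpose(0, 2, 1))


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, x.shape, training)
        return self.params["gamma"][None, :, None] * xhat + self.params["beta"][None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape, training = self._cache
        n = shape[0] * shape[2]
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2))
        self.grads["beta"] = dy.sum(axis=(0, 2))
        g = self.params["gamma"][None, :, None] * inv[None, :, None]
        if not training:
            return (dy * g).astype(DTYPE)
        dy_sum = dy.sum(axis=(0, 2))[None, :, None]
        dyxhat_sum = (dy * xhat).sum(axis=(0, 2))[None, :, None]
        return (g * (dy - dy_sum / n - xhat * dyxhat_sum / n)).astype(DTYPE)


class Tanh(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = np.tanh(x)
        self._cache = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y = self._cache
        return dy * (1.0 - y * y)


class ClampedTanh(Layer):
    """max(0, tanh(x)): squashes to [0, 1] with an exact point mass at zero."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        t = np.tanh(x)
        y = np.maximum(t, 0.0)
        self._cache = t
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        t = self._cache
        return dy * (1.0 - t * t) * (t > 0)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, parameters, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.parameters = parameters
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[name]) for layer, name in parameters]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in parameters]

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for i, (layer, name) in enumerate(self.parameters):
            g = layer.grads[name].astype(DTYPE)
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1c
            vhat = self.v[i] / b2c
            layer.params[name] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
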