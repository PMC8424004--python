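"""Minimal convolutional neural network with manual backpropagation.

Implements exactly the layer set the Q-network needs — 2D convolution
(valid padding, stride 1), 2x2 max pooling, dropout, flatten, dense — plus
the Adam optimiser and mean-squared-error loss, all in float32 numpy.
Convolutions are evaluated as a sum of nine shifted matrix products, which
is fast for 3x3 kernels without materialising an im2col buffer.

Data layout is channels-last: batches are (N, H, W, C).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "MaxPool2x2",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "mse_loss",
]

_F32 = np.float32


class Layer:
    """Base layer: forward/backward plus flat parameter access."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class Conv2D(Layer):
    """3x3 (or kxk) valid convolution, optional ReLU."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        activation: str | None = "relu",
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        k = kernel_size
        fan_in = k * k * in_channels
        scale = np.sqrt(2.0 / fan_in)
        self.w = (rng.standard_normal((k, k, in_channels, out_channels)) * scale).astype(_F32)
        self.b = np.zeros(out_channels, dtype=_F32)
        self.k = k
        self.activation = activation
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.k
        n, h, w_, c = x.shape
        oh, ow = h - k + 1, w_ - k + 1
        if oh <= 0 or ow <= 0:
            raise ValueError(f"input {x.shape} too small for {k}x{k} convolution")
        out = np.tile(self.b, (n, oh, ow, 1)).astype(_F32)
        for di in range(k):
            for dj in range(k):
                out += x[:, di: di + oh, dj: dj + ow, :] @ self.w[di, dj]
        self._x = x
        self._pre = out
        return _relu(out) if self.activation == "relu" else out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            grad_out = grad_out * (self._pre > 0)
        x = self._x
        k = self.k
        n, oh, ow, f = grad_out.shape
        self.grads[1][...] = grad_out.sum(axis=(0, 1, 2))
        dx = np.zeros_like(x)
        g2 = grad_out.reshape(-1, f)
        for di in range(k):
            for dj in range(k):
                patch = x[:, di: di + oh, dj: dj + ow, :].reshape(-1, x.shape[3])
                self.grads[0][di, dj] = patch.T @ g2
                dx[:, di: di + oh, dj: dj + ow, :] += grad_out @ self.w[di, dj].T
        return dx


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        xt = x[:, : oh * 2, : ow * 2, :].reshape(n, oh, 2, ow, 2, c)
        flat = xt.transpose(0, 1, 3, 5, 2, 4).reshape(n, oh, ow, c, 4)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._x_shape = x.shape
        # one-hot winner per window: ties must not duplicate gradient
        # (with ReLU inputs, all-zero windows tie on every element)
        self._onehot = (np.arange(4) == arg[..., None])
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, oh, ow, c = grad_out.shape
        g = self._onehot * grad_out[..., None]  # (n, oh, ow, c, 4)
        g = g.reshape(n, oh, ow, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros(self._x_shape, dtype=grad_out.dtype)
        dx[:, : oh * 2, : ow * 2, :] = g.reshape(n, oh * 2, ow * 2, c)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at prediction time."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out if self._mask is None else grad_out * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(self._shape)


class Dense(Layer):
    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        activation: str | None = None,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_dim)
        self.w = (rng.standard_normal((in_dim, out_dim)) * scale).astype(_F32)
        self.b = np.zeros(out_dim, dtype=_F32)
        self.activation = activation
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        pre = x @ self.w + self.b
        self._pre = pre
        return _relu(pre) if self.activation == "relu" else pre

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            grad_out = grad_out * (self._pre > 0)
        self.grads[0][...] = self._x.T @ grad_out
        self.grads[1][...] = grad_out.sum(axis=0)
        return grad_out @ self.w.T


class Sequential:
    """A feed-forward stack of layers."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    __call__ = forward

    def backward(self, grad_out: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        if len(weights) != len(self.params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(self.params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w


class Adam:
    """Adam optimiser over a parameter list (in-place updates)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)

    def state(self) -> dict:
        return {
            "t": self.t,
            "m": [a.copy() for a in self.m],
            "v": [a.copy() for a in self.v],
            "lr": self.lr,
        }

    def load_state(self, state: dict) -> None:
        self.t = state["t"]
        for dst, src in zip(self.m, state["m"]):
            dst[...] = src
        for dst, src in zip(self.v, state["v"]):
            dst[...] = src
        self.lr = state["lr"]


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all entries and its gradient w.r.t. pred."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(pred.dtype)
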