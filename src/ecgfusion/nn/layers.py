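"""Differentiable layers. Tensors are (batch, time, channels) or (batch, features)."""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base layer; stateless layers leave params/grads empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """1-D convolution along time, kernel 3x1 by default, 'same' padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(kernel_size, in_channels, out_channels)
        ).astype(DTYPE)
        self.params["b"] = np.zeros(out_channels, dtype=DTYPE)
        self._xp: np.ndarray | None = None

    def forward(self, x, train=False, rng=None):
        k = self.kernel_size
        pad = k // 2
        xp = np.pad(x.astype(DTYPE, copy=False), ((0, 0), (pad, pad), (0, 0)))
        L = x.shape[1]
        W, b = self.params["W"], self.params["b"]
        y = np.zeros((x.shape[0], L, self.out_channels), dtype=DTYPE)
        for o in range(k):
            y += xp[:, o:o + L, :] @ W[o]
        y += b
        self._xp = xp
        return y

    def backward(self, dy):
        k = self.kernel_size
        pad = k // 2
        xp = self._xp
        L = dy.shape[1]
        W = self.params["W"]
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        for o in range(k):
            dW[o] = np.tensordot(xp[:, o:o + L, :], dy, axes=([0, 1], [0, 1]))
            dxp[:, o:o + L, :] += dy @ W[o].T
        self.grads["W"] = dW
        self.grads["b"] = dy.sum(axis=(0, 1))
        return dxp[:, pad:pad + L, :] if pad else dxp


class MaxPool1D(Layer):
    """Max pooling along time; a trailing odd sample is dropped."""

    def __init__(self, pool_size: int = 2) -> None:
        super().__init__()
        self.pool_size = pool_size
        self._mask: np.ndarray | None = None
        self._in_len = 0

    def forward(self, x, train=False, rng=None):
        p = self.pool_size
        self._in_len = x.shape[1]
        L = (x.shape[1] // p) * p
        xr = x[:, :L, :].reshape(x.shape[0], L // p, p, x.shape[2])
        idx = xr.argmax(axis=2)
        self._mask = idx
        return np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        p = self.pool_size
        B, Lp, C = dy.shape
        dxr = np.zeros((B, Lp, p, C), dtype=dy.dtype)
        np.put_along_axis(dxr, self._mask[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((B, self._in_len, C), dtype=dy.dtype)
        dx[:, :Lp * p, :] = dxr.reshape(B, Lp * p, C)
        return dx


class BatchNorm1D(Layer):
    """Per-channel batch normalization over batch and time axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache: tuple | None = None

    def forward(self, x, train=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(DTYPE)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, axes, x.shape)
        return (self.params["gamma"] * xhat + self.params["beta"]).astype(DTYPE)

    def backward(self, dy):
        xhat, inv_std, axes, shape = self._cache
        n = np.prod([shape[a] for a in axes])
        gamma = self.params["gamma"]
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        # standard batchnorm gradient (training-mode statistics)
        dxhat = dy * gamma
        dx = (
            dxhat
            - dxhat.mean(axis=axes)
            - xhat * (dxhat * xhat).mean(axis=axes)
        ) * inv_std
        return dx.astype(DTYPE)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class GlobalAvgPool1D(Layer):
    """Average over the time axis: (B, L, C) -> (B, C)."""

    def forward(self, x, train=False, rng=None):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :] / self._L, self._L, axis=1)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng()
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features)
        ).astype(DTYPE)
        self.params["b"] = np.zeros(out_features, dtype=DTYPE)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.uniform(size=x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask
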