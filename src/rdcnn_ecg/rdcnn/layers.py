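"""Differentiable layer primitives over (batch, length, channels) arrays.

Each layer carries its trainable arrays in ``params`` and the matching
gradients in ``grads``; ``forward`` caches whatever ``backward`` needs.
Convolutions use stride-1 same padding (im2col via stride tricks), so
every spatial operator except pooling preserves beat length.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: parameterless identity with the common bookkeeping."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.state: dict[str, np.ndarray] = {}  # non-trainable (BN stats)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv1D(Layer):
    """Stride-1 'same' 1-D convolution, weights He-initialized from fan-in."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        bias: bool = True,
    ) -> None:
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel // 2
        fan_in = kernel * c_in
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(kernel * c_in, c_out)
        )
        self.has_bias = bias
        if bias:
            self.params["b"] = np.zeros(c_out)

    def _cols(self, xp: np.ndarray, length: int) -> np.ndarray:
        # (N, L, C, k) view -> (N*L, k*C) matching the (k-major, C) W layout
        win = sliding_window_view(xp, self.kernel, axis=1)
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            -1, self.kernel * self.c_in
        )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, length, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        cols = self._cols(xp, length)
        out = cols @ self.params["W"]
        if self.has_bias:
            out += self.params["b"]
        self._cache = (xp, length, n)
        return out.reshape(n, length, self.c_out)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xp, length, n = self._cache
        g2 = g.reshape(-1, self.c_out)
        cols = self._cols(xp, length)
        self.grads["W"] = cols.T @ g2
        if self.has_bias:
            self.grads["b"] = g2.sum(axis=0)
        gcols = (g2 @ self.params["W"].T).reshape(
            n, length, self.kernel, self.c_in
        )
        gxp = np.zeros_like(xp)
        for t in range(self.kernel):
            gxp[:, t : t + length, :] += gcols[:, :, t, :]
        return gxp[:, self.pad_left : self.pad_left + length, :]


class BatchNorm1D(Layer):
    """Per-channel batch normalization over the (batch, length) axes."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(c)
        self.params["beta"] = np.zeros(c)
        self.state["running_mean"] = np.zeros(c)
        self.state["running_var"] = np.ones(c)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            m = self.momentum
            self.state["running_mean"] = m * self.state["running_mean"] + (1 - m) * mean
            self.state["running_var"] = m * self.state["running_var"] + (1 - m) * var
        else:
            mean = self.state["running_mean"]
            var = self.state["running_var"]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, x.shape[0] * x.shape[1], training)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv_std, m, training = self._cache
        self.grads["gamma"] = (g * xhat).sum(axis=(0, 1))
        self.grads["beta"] = g.sum(axis=(0, 1))
        gxhat = g * self.params["gamma"]
        if not training:
            return gxhat * inv_std
        return (
            inv_std
            / m
            * (
                m * gxhat
                - gxhat.sum(axis=(0, 1))
                - xhat * (gxhat * xhat).sum(axis=(0, 1))
            )
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class MaxPool1D(Layer):
    """Temporal max pooling; output length (L - pool) // stride + 1."""

    def __init__(self, pool: int = 2, stride: int = 2) -> None:
        super().__init__()
        self.pool, self.stride = pool, stride

    def out_length(self, length: int) -> int:
        return (length - self.pool) // self.stride + 1

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        win = sliding_window_view(x, self.pool, axis=1)[:, :: self.stride]
        # win: (N, Lout, C, pool)
        self._arg = win.argmax(axis=-1)
        self._in_shape = x.shape
        return win.max(axis=-1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        gx = np.zeros(self._in_shape)
        lout = g.shape[1]
        starts = np.arange(lout) * self.stride
        for p in range(self.pool):
            sel = self._arg == p
            gx[:, starts + p, :] += g * sel
        return gx


class GlobalAvgPool(Layer):
    """Mean over the temporal axis: (N, L, C) -> (N, C)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._length = x.shape[1]
        return x.mean(axis=1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.repeat(g[:, None, :] / self._length, self._length, axis=1)


class Dense(Layer):
    """Fully-connected layer on (N, features) arrays."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params["b"] = np.zeros(n_out)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ g
        self.grads["b"] = g.sum(axis=0)
        return g @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return g
        return g * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n
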