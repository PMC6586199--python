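"""Layer primitives with explicit forward/backward passes.

Every layer exposes ``forward(x, training)`` and ``backward(dy)`` (which
returns the gradient w.r.t. the layer input), plus ``params`` / ``grads``
dictionaries for the optimizer. Convolutions use valid padding only:
inputs are already zero-padded to a fixed shape upstream.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int, dtype=np.float32) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base class; stateless layers keep empty param dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Valid-padding 1D convolution via im2col + matrix multiply.

    Input ``(n, L, c_in)`` -> output ``(n, L - k + 1, c_out)``. The kernel
    is stored as ``(k, c_in, c_out)``.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.params = {
            "W": glorot_uniform(rng, (kernel, c_in, c_out),
                                fan_in=kernel * c_in, fan_out=kernel * c_out,
                                dtype=dtype),
            "b": np.zeros(c_out, dtype=dtype),
        }

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, length, _ = x.shape
        l_out = length - self.kernel + 1
        if l_out < 1:
            raise ValueError(
                f"input length {length} shorter than kernel {self.kernel}")
        cols = np.empty((n, l_out, self.kernel * self.c_in), dtype=x.dtype)
        for j in range(self.kernel):
            cols[:, :, j * self.c_in:(j + 1) * self.c_in] = x[:, j:j + l_out, :]
        self._cols = cols
        self._in_length = length
        w2 = self.params["W"].reshape(self.kernel * self.c_in, self.c_out)
        return cols @ w2 + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, l_out, _ = dy.shape
        cols2 = self._cols.reshape(n * l_out, -1)
        dy2 = dy.reshape(n * l_out, self.c_out)
        self.grads["W"] = (cols2.T @ dy2).reshape(self.params["W"].shape)
        self.grads["b"] = dy2.sum(axis=0)
        dx = np.zeros((n, self._in_length, self.c_in), dtype=dy.dtype)
        w = self.params["W"]
        for j in range(self.kernel):
            dx[:, j:j + l_out, :] += dy @ w[j].T
        self._cols = None
        return dx


class OneHotConv1D(Conv1D):
    """First-layer convolution over one-hot rows, fed by integer index
    tracks instead of dense matrices.

    The input is an ``(n, L)`` int array giving, per row of the implied
    one-hot matrix, the column of its single 1 (or -1 for an all-zero
    row). Numerically identical to :class:`Conv1D` on the corresponding
    dense one-hot input, but computed via a sparse im2col matrix, and —
    being an input layer — it returns no input gradient.
    """

    def forward(self, track: np.ndarray, training: bool) -> np.ndarray:
        if track.ndim != 2:
            raise ValueError("OneHotConv1D expects an (n, L) index track")
        n, length = track.shape
        k, c = self.kernel, self.c_in
        l_out = length - k + 1
        if l_out < 1:
            raise ValueError(
                f"input length {length} shorter than kernel {self.kernel}")
        # -1 (zero row) is remapped onto a zero padding row of the kernel
        padded = np.where(track < 0, c, track).astype(np.int32)
        col_idx = np.empty((n, l_out, k), dtype=np.int32)
        for j in range(k):
            col_idx[:, :, j] = j * (c + 1) + padded[:, j:j + l_out]
        nnz = n * l_out * k
        self._sparse_cols = sp.csr_matrix(
            (np.ones(nnz, dtype=self.params["W"].dtype), col_idx.ravel(),
             np.arange(0, nnz + 1, k)),
            shape=(n * l_out, k * (c + 1)))
        self._out_shape = (n, l_out, self.c_out)
        w_pad = self._padded_kernel()
        y = (self._sparse_cols @ w_pad).reshape(self._out_shape)
        return y + self.params["b"]

    def _padded_kernel(self) -> np.ndarray:
        w = self.params["W"]
        w_pad = np.concatenate(
            [w, np.zeros((self.kernel, 1, self.c_out), dtype=w.dtype)], axis=1)
        return w_pad.reshape(self.kernel * (self.c_in + 1), self.c_out)

    def backward(self, dy: np.ndarray) -> None:
        n, l_out, _ = dy.shape
        dy2 = dy.reshape(n * l_out, self.c_out)
        dw_pad = (self._sparse_cols.T @ dy2).reshape(
            self.kernel, self.c_in + 1, self.c_out)
        self.grads["W"] = np.ascontiguousarray(dw_pad[:, : self.c_in, :])
        self.grads["b"] = dy2.sum(axis=0)
        self._sparse_cols = None
        return None  # input layer: no gradient w.r.t. the sequence


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling; trailing remainder positions dropped."""

    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, length, c = x.shape
        l_out = length // self.pool
        xr = x[:, : l_out * self.pool, :].reshape(n, l_out, self.pool, c)
        y = xr.max(axis=2)
        if training:
            self._xr = xr
            self._y = y
            self._in_shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # route gradient to every argmax position (equality mask); ties
        # only arise at exact value collisions, which the preceding ReLU
        # zeroes out in practice
        n, l_out, c = dy.shape
        dxr = (self._xr == self._y[:, :, None, :]) * dy[:, :, None, :]
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, : l_out * self.pool, :] = dxr.reshape(n, l_out * self.pool, c)
        self._xr = self._y = None
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over the batch and length axes."""

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-3, dtype=np.float32) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {
            "gamma": np.ones(channels, dtype=dtype),
            "beta": np.zeros(channels, dtype=dtype),
        }
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            m = self.momentum
            self.running_mean = (m * self.running_mean
                                 + (1 - m) * mean).astype(x.dtype)
            self.running_var = (m * self.running_var
                                + (1 - m) * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._m = x.shape[0] * x.shape[1]
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, m = self._xhat, self._m
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 1))
        self.grads["beta"] = dy.sum(axis=(0, 1))
        dxhat = dy * self.params["gamma"]
        # standard batchnorm gradient, vectorised per channel
        dx = (dxhat
              - dxhat.mean(axis=(0, 1))
              - xhat * (dxhat * xhat).mean(axis=(0, 1))) / self._std
        self._xhat = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class GlobalAvgPool(Layer):
    """Mean over the length axis: (n, L, c) -> (n, c)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._length = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, None, :] / self._length, self._length, axis=1)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.params = {
            "W": glorot_uniform(rng, (d_in, d_out), d_in, d_out, dtype=dtype),
            "b": np.zeros(d_out, dtype=dtype),
        }

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        dx = dy @ self.params["W"].T
        self._x = None
        return dx


class Concatenate(Layer):
    """Joins two feature vectors along the last axis."""

    def forward_pair(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        self._split = a.shape[-1]
        return np.concatenate([a, b], axis=-1)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return dy[..., : self._split], dy[..., self._split:]
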