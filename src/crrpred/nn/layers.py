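"""Minimal feed-forward / convolutional layer kit with manual backprop.

Layers expose ``forward(x, train)`` and ``backward(grad)`` and collect
their parameters and gradients in ``params`` / ``grads`` (matching
lists of arrays). Convolutions use same-padding and stride 1; pooling
uses non-overlapping windows and discards the remainder. All arrays are
float32 unless noted.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Dense", "ReLU", "Sigmoid", "Dropout", "Flatten",
    "BatchNorm", "Conv1D", "Conv2D", "MaxPool1D", "AvgPool1D", "MaxPool2D",
]


class Layer:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def summary(self) -> str:
        return type(self).__name__


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = _glorot(rng, (in_dim, out_dim), in_dim, out_dim)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T

    def summary(self):
        return f"Dense({self.W.shape[0]}->{self.W.shape[1]})"

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x, train):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate {rate} outside [0, 1)")
        self.rate = rate
        self._rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask

    def summary(self):
        return f"Dropout({self.rate})"


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class BatchNorm(Layer):
    """Batch normalization over all axes except the last (features/channels)."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(dim, dtype=np.float32)
        self.beta = np.zeros(dim, dtype=np.float32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(dim, dtype=np.float32)
        self.running_var = np.ones(dim, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._n = x.size // x.shape[-1]
            self._xhat = (x - mean) / np.sqrt(var + self.eps)
            self._istd = 1.0 / np.sqrt(var + self.eps)
            return self.gamma * self._xhat + self.beta
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma * xhat + self.beta

    def backward(self, grad):
        axes = tuple(range(grad.ndim - 1))
        self.grads[0][...] = (grad * self._xhat).sum(axis=axes)
        self.grads[1][...] = grad.sum(axis=axes)
        n = self._n
        gx = self.gamma * grad
        return self._istd / n * (
            n * gx
            - gx.sum(axis=axes)
            - self._xhat * (gx * self._xhat).sum(axis=axes)
        )

    def summary(self):
        return f"BatchNorm({self.gamma.size})"


def _pad_same_1d(x: np.ndarray, kernel: int) -> tuple[np.ndarray, int]:
    total = kernel - 1
    left = total // 2
    return np.pad(x, ((0, 0), (left, total - left), (0, 0))), left


class Conv1D(Layer):
    """Same-padded, stride-1 1-D convolution over (n, length, channels)."""

    def __init__(self, in_ch: int, filters: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.W = _glorot(rng, (kernel * in_ch, filters), kernel * in_ch, filters)
        self.b = np.zeros(filters, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.in_ch = in_ch
        self.filters = filters

    def _im2col(self, xp: np.ndarray, length: int) -> np.ndarray:
        n, _, c = xp.shape
        s0, s1, s2 = xp.strides
        cols = np.lib.stride_tricks.as_strided(
            xp, shape=(n, length, self.kernel, c), strides=(s0, s1, s1, s2)
        )
        return cols.reshape(n * length, self.kernel * c)

    def forward(self, x, train):
        n, length, _ = x.shape
        xp, self._left = _pad_same_1d(x, self.kernel)
        self._xp_shape = xp.shape
        self._cols = self._im2col(xp, length)
        out = self._cols @ self.W + self.b
        return out.reshape(n, length, self.filters)

    def backward(self, grad):
        n, length, f = grad.shape
        g2 = grad.reshape(n * length, f)
        self.grads[0][...] = self._cols.T @ g2
        self.grads[1][...] = g2.sum(axis=0)
        gcols = (g2 @ self.W.T).reshape(n, length, self.kernel, self.in_ch)
        gxp = np.zeros(self._xp_shape, dtype=grad.dtype)
        for k in range(self.kernel):
            gxp[:, k:k + length, :] += gcols[:, :, k, :]
        return gxp[:, self._left:self._left + length, :]

    def summary(self):
        return f"Conv1D({self.filters}xk{self.kernel})"


class Conv2D(Layer):
    """Same-padded, stride-1 2-D convolution over (n, H, W, channels)."""

    def __init__(self, in_ch: int, filters: int, kernel: tuple[int, int], rng: np.random.Generator):
        self.kh, self.kw = kernel
        fan = self.kh * self.kw * in_ch
        self.W = _glorot(rng, (fan, filters), fan, filters)
        self.b = np.zeros(filters, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.in_ch = in_ch
        self.filters = filters

    def forward(self, x, train):
        n, H, W, _ = x.shape
        ph, pw = self.kh - 1, self.kw - 1
        self._pads = (ph // 2, pw // 2)
        xp = np.pad(x, ((0, 0), (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2), (0, 0)))
        self._xp_shape = xp.shape
        s0, s1, s2, s3 = xp.strides
        cols = np.lib.stride_tricks.as_strided(
            xp, shape=(n, H, W, self.kh, self.kw, self.in_ch),
            strides=(s0, s1, s2, s1, s2, s3),
        )
        self._cols = cols.reshape(n * H * W, self.kh * self.kw * self.in_ch)
        out = self._cols @ self.W + self.b
        return out.reshape(n, H, W, self.filters)

    def backward(self, grad):
        n, H, W, f = grad.shape
        g2 = grad.reshape(n * H * W, f)
        self.grads[0][...] = self._cols.T @ g2
        self.grads[1][...] = g2.sum(axis=0)
        gcols = (g2 @ self.W.T).reshape(n, H, W, self.kh, self.kw, self.in_ch)
        gxp = np.zeros(self._xp_shape, dtype=grad.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                gxp[:, i:i + H, j:j + W, :] += gcols[:, :, :, i, j, :]
        ph, pw = self._pads
        return gxp[:, ph:ph + H, pw:pw + W, :]

    def summary(self):
        return f"Conv2D({self.filters}xk{self.kh}x{self.kw})"


class MaxPool1D(Layer):
    def __init__(self, size: int):
        self.size = size

    def forward(self, x, train):
        n, length, c = x.shape
        out_len = length // self.size
        self._in_len = length
        xt = x[:, : out_len * self.size, :].reshape(n, out_len, self.size, c)
        self._argmax = xt.argmax(axis=2)
        return xt.max(axis=2)

    def backward(self, grad):
        n, out_len, c = grad.shape
        gx = np.zeros((n, out_len, self.size, c), dtype=grad.dtype)
        ni, oi, ci = np.ogrid[:n, :out_len, :c]
        gx[ni, oi, self._argmax, ci] = grad
        gx = gx.reshape(n, out_len * self.size, c)
        if out_len * self.size < self._in_len:
            gx = np.pad(gx, ((0, 0), (0, self._in_len - out_len * self.size), (0, 0)))
        return gx

    def summary(self):
        return f"MaxPool1D({self.size})"


class AvgPool1D(Layer):
    def __init__(self, size: int):
        self.size = size

    def forward(self, x, train):
        n, length, c = x.shape
        out_len = length // self.size
        self._in_len = length
        return x[:, : out_len * self.size, :].reshape(n, out_len, self.size, c).mean(axis=2)

    def backward(self, grad):
        n, out_len, c = grad.shape
        gx = np.repeat(grad / self.size, self.size, axis=1)
        if gx.shape[1] < self._in_len:
            gx = np.pad(gx, ((0, 0), (0, self._in_len - gx.shape[1]), (0, 0)))
        return gx

    def summary(self):
        return f"AvgPool1D({self.size})"


class MaxPool2D(Layer):
    def __init__(self, size: tuple[int, int]):
        self.sh, self.sw = size

    def forward(self, x, train):
        n, H, W, c = x.shape
        oh, ow = max(H // self.sh, 1), max(W // self.sw, 1)
        sh, sw = min(self.sh, H), min(self.sw, W)
        self._shape = x.shape
        self._eff = (sh, sw, oh, ow)
        xt = x[:, : oh * sh, : ow * sw, :].reshape(n, oh, sh, ow, sw, c)
        xt = xt.transpose(0, 1, 3, 2, 4, 5).reshape(n, oh, ow, sh * sw, c)
        self._argmax = xt.argmax(axis=3)
        return xt.max(axis=3)

    def backward(self, grad):
        n, H, W, c = self._shape
        sh, sw, oh, ow = self._eff
        gx = np.zeros((n, oh, ow, sh * sw, c), dtype=grad.dtype)
        ni, hi, wi, ci = np.ogrid[:n, :oh, :ow, :c]
        gx[ni, hi, wi, self._argmax, ci] = grad
        gx = gx.reshape(n, oh, ow, sh, sw, c).transpose(0, 1, 3, 2, 4, 5)
        gx = gx.reshape(n, oh * sh, ow * sw, c)
        out = np.zeros(self._shape, dtype=grad.dtype)
        out[:, : oh * sh, : ow * sw, :] = gx
        return out

    def summary(self):
        return f"MaxPool2D({self.sh}x{self.sw})"
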