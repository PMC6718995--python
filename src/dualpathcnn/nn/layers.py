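"""Differentiable layers on NHWC float32 tensors.

Convolutions are computed by accumulating one matmul per kernel offset, which
keeps memory at one feature map instead of a full im2col buffer while still
going through BLAS.  Each layer caches what its backward pass needs; calling
``backward`` before ``forward`` is a programming error.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def xavier_normal(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier normal initialization: sd = sqrt(2 / (fan_in + fan_out))."""
    sd = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, sd, size=shape).astype(F32)


class Conv2d:
    """Square-kernel 2D convolution, NHWC, weight layout (k, k, C_in, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, padding: int,
                 rng: np.random.Generator):
        self.k, self.s, self.p = kernel, stride, padding
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel * kernel
        fan_out = c_out * kernel * kernel
        self.W = xavier_normal(rng, (kernel, kernel, c_in, c_out), fan_in, fan_out)
        self.b = np.zeros(c_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        # (array, grad, weight_decay applies)
        return [(self.W, self.dW, True), (self.b, self.db, False)]

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        ho = (h - self.k + 2 * self.p) // self.s + 1
        wo = (w - self.k + 2 * self.p) // self.s + 1
        return ho, wo

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, _ = x.shape
        ho, wo = self.out_hw(h, w)
        if self.p:
            xp = np.zeros((n, h + 2 * self.p, w + 2 * self.p, self.c_in), dtype=F32)
            xp[:, self.p:self.p + h, self.p:self.p + w, :] = x
        else:
            xp = x
        y = np.empty((n, ho, wo, self.c_out), dtype=F32)
        y[:] = self.b
        for i in range(self.k):
            for j in range(self.k):
                xs = xp[:, i:i + ho * self.s:self.s, j:j + wo * self.s:self.s, :]
                y += xs @ self.W[i, j]
        self._xp_shape = xp.shape
        self._xp = xp
        self._in_hw = (h, w)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, ho, wo, _ = dy.shape
        h, w = self._in_hw
        xp = self._xp
        dxp = np.zeros(self._xp_shape, dtype=F32)
        for i in range(self.k):
            for j in range(self.k):
                xs = xp[:, i:i + ho * self.s:self.s, j:j + wo * self.s:self.s, :]
                self.dW[i, j] = np.tensordot(xs, dy, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, i:i + ho * self.s:self.s, j:j + wo * self.s:self.s, :] += dy @ self.W[i, j].T
        self.db[:] = dy.sum(axis=(0, 1, 2))
        self._xp = None
        if self.p:
            return dxp[:, self.p:self.p + h, self.p:self.p + w, :]
        return dxp


class BatchNorm:
    """Per-channel batch normalization over (N, H, W).

    Running statistics use momentum 0.9 (running = 0.9*running + 0.1*batch)
    and epsilon 1e-5; evaluation mode normalizes by the running statistics.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9):
        self.eps, self.momentum = eps, momentum
        self.gamma = np.ones(channels, dtype=F32)
        self.beta = np.zeros(channels, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)

    def params(self):
        return [(self.gamma, self.dgamma, False), (self.beta, self.dbeta, False)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(F32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * ivar
        if train:
            self._xhat = xhat.astype(F32)
            self._ivar = ivar.astype(F32)
            self._m = int(np.prod([x.shape[a] for a in axes]))
        return (self.gamma * xhat + self.beta).astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = tuple(range(dy.ndim - 1))
        xhat, ivar, m = self._xhat, self._ivar, self._m
        self.dbeta[:] = dy.sum(axis=axes)
        self.dgamma[:] = (dy * xhat).sum(axis=axes)
        dx = (self.gamma * ivar / m) * (m * dy - self.dbeta - xhat * self.dgamma)
        self._xhat = None
        return dx.astype(F32)


class ReLU:
    """f(x) = max(0, x): outputs 0 for negative input."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0)
        self._mask = y > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool3x3s2:
    """3x3 max pooling, stride 2, padding 1 (the reduction-module pool branch)."""

    k, s, p = 3, 2, 1

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        ho = (h - self.k + 2 * self.p) // self.s + 1
        wo = (w - self.k + 2 * self.p) // self.s + 1
        xp = np.full((n, h + 2, w + 2, c), -np.inf, dtype=F32)
        xp[:, 1:1 + h, 1:1 + w, :] = x
        y = np.full((n, ho, wo, c), -np.inf, dtype=F32)
        arg = np.zeros((n, ho, wo, c), dtype=np.int8)
        for i in range(3):
            for j in range(3):
                xs = xp[:, i:i + ho * 2:2, j:j + wo * 2:2, :]
                better = xs > y
                y = np.where(better, xs, y)
                arg = np.where(better, np.int8(3 * i + j), arg)
        self._arg = arg
        self._in_shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        ho, wo = dy.shape[1:3]
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=F32)
        for i in range(3):
            for j in range(3):
                mask = self._arg == 3 * i + j
                dxp[:, i:i + ho * 2:2, j:j + wo * 2:2, :] += dy * mask
        self._arg = None
        return dxp[:, 1:1 + h, 1:1 + w, :]


class GlobalAvgPool:
    """Average each feature map to one value: (N, H, W, C) -> (N, C)."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w), (n, h, w, c)).astype(F32)


class Linear:
    """Fully connected layer (N, F) -> (N, K), Xavier-initialized, zero bias."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = xavier_normal(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW, True), (self.b, self.db, False)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW[:] = self._x.T @ dy
        self.db[:] = dy.sum(axis=0)
        dx = dy @ self.W.T
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean())
    dlogits = probs
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(F32)
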