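"""Minimal NumPy neural-network layers with explicit backpropagation.

Only what the convolutional auto-encoder needs: 3x3 convolutions (stride 1
or 2, padding 1), batch normalisation, ReLU, factor-2 nearest-neighbour
up-sampling, a Sequential container and an Adam optimiser.  Every layer
implements ``forward(x, train)`` and ``backward(grad)``; parameters are
``Param`` objects carrying their gradient, so training is a plain loop of
forward, backward, ``Adam.step()``.

All computation is float32 NumPy (the layers are memory-bandwidth-bound on
CPU, and single precision is standard for convolutional training); runs are
bit-reproducible for a fixed seed on one machine.
"""

from __future__ import annotations

import numpy as np

#: Working precision of all layers and optimiser state.
DTYPE = np.float32

__all__ = [
    "DTYPE",
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "UpsampleNearest2x",
    "Sequential",
    "Adam",
]


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (or k x k) convolution, 'same' padding, arbitrary stride.

    He-normal weight initialisation.  Forward and backward are evaluated
    through an im2col layout so each pass is one BLAS matmul; the column
    matrix is rebuilt in backward rather than cached, trading a little time
    for a much smaller memory high-water mark.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.W = Param(rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)))
        self.b = Param(np.zeros(c_out))
        self.stride, self.pad, self.kernel = stride, pad, kernel
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.kernel, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def _im2col(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        """(B, C, Hp, Wp) → (B*ho*wo, C*k*k) patch matrix."""
        b, c = xp.shape[:2]
        k, s = self.kernel, self.stride
        cols = np.empty((b, ho, wo, c, k, k), dtype=xp.dtype)
        for di in range(k):
            for dj in range(k):
                cols[:, :, :, :, di, dj] = xp[
                    :, :, di : di + s * ho : s, dj : dj + s * wo : s
                ].transpose(0, 2, 3, 1)
        return cols.reshape(b * ho * wo, c * k * k)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        s, p = self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho, wo = self._out_hw(x.shape[2], x.shape[3])
        c_out = self.W.value.shape[0]
        cols = self._im2col(xp, ho, wo)
        out = cols @ self.W.value.reshape(c_out, -1).T + self.b.value
        if train:
            self._xp = xp
        return out.reshape(x.shape[0], ho, wo, c_out).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._xp is not None, "backward() before forward(train=True)"
        s, p, k = self.stride, self.pad, self.kernel
        xp, self._xp = self._xp, None
        b, c_out, ho, wo = grad.shape
        c_in = xp.shape[1]
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(-1, c_out)
        cols = self._im2col(xp, ho, wo)
        self.W.grad += (g2.T @ cols).reshape(self.W.value.shape)
        self.b.grad += g2.sum(axis=0)
        gcols = (g2 @ self.W.value.reshape(c_out, -1)).reshape(b, ho, wo, c_in, k, k)
        gxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                gxp[:, :, di : di + s * ho : s, dj : dj + s * wo : s] += (
                    gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
                )
        if p:
            return gxp[:, :, p:-p, p:-p]
        return gxp


class BatchNorm2d(Layer):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0, 2, 3)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) / std[None, :, None, None]
        if train:
            self._cache = (xhat, std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        self._cache = None
        axes = (0, 2, 3)
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value[None, :, None, None]
        gsum = g.sum(axis=axes, keepdims=True)
        gx_sum = (g * xhat).sum(axis=axes, keepdims=True)
        return (g - gsum / n - xhat * gx_sum / n) / std[None, :, None, None]


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return grad * mask


class UpsampleNearest2x(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, h, w = grad.shape
        return grad.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam optimiser with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad**2 - v)
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
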