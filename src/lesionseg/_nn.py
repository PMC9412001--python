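"""Minimal CPU neural-network engine: layers with explicit forward/backward.

NCHW layout throughout: arrays are (batch, channels, height, width) float32.
Each layer stores its parameters in ``.params`` and the matching gradients in
``.grads`` (same keys); ``forward(x, train)`` caches what ``backward(grad)``
needs. Convolutions use im2col + BLAS matmul, which is fast enough for the
slice sizes this package trains at.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D", "BatchNorm2D", "ReLU", "MaxPool2", "ConvTranspose2",
    "SGDMomentum", "softmax_channels",
]


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """k×k convolution with "same" zero padding (k odd), He-normal init."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, fan_in)).astype(np.float32),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """(B, C, H, W) → (B, k·k·C, H·W); block m=(i·k+j) holds xp shifted
        by (i, j)."""
        k, p = self.k, self.k // 2
        b, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = np.empty((b, k * k * c, h * w), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                m = i * k + j
                cols[:, m * c:(m + 1) * c] = \
                    xp[:, :, i:i + h, j:j + w].reshape(b, c, h * w)
        return cols

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        if not x.flags.c_contiguous:
            x = np.ascontiguousarray(x)
        cols = self._im2col(x)
        y = np.matmul(self.params["W"], cols)  # (B, Cout, H·W)
        y += self.params["b"][None, :, None]
        self._cache = (cols, x.shape)
        return y.reshape(b, self.c_out, h, w)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        b, c, h, w = xshape
        k, p = self.k, self.k // 2
        gy = np.ascontiguousarray(grad).reshape(b, self.c_out, h * w)
        self.grads["W"] += np.matmul(gy, cols.transpose(0, 2, 1)).sum(axis=0)
        self.grads["b"] += gy.sum(axis=(0, 2))
        dcols = np.matmul(self.params["W"].T, gy)  # (B, k·k·C, H·W)
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=dcols.dtype)
        for i in range(k):
            for j in range(k):
                m = i * k + j
                dxp[:, :, i:i + h, j:j + w] += \
                    dcols[:, m * c:(m + 1) * c].reshape(b, c, h, w)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2D(Layer):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(c, dtype=np.float32),
                       "beta": np.zeros(c, dtype=np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return (self.params["gamma"][None, :, None, None] * xhat
                + self.params["beta"][None, :, None, None])

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n = shape[0] * shape[2] * shape[3]
        self.grads["gamma"] += (grad * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += grad.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = grad * g
        # standard batchnorm backward (training statistics)
        term = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return term * inv[None, :, None, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2(Layer):
    """2×2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(b, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        dxr = np.zeros((b, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(dxr, self._idx[..., None], grad[..., None], axis=-1)
        dxr = dxr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(b, c, h, w)


class ConvTranspose2(Layer):
    """2×2 transpose convolution, stride 2 (exact 2× upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / c_in),
                            size=(c_in, c_out, 2, 2)).astype(np.float32),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h * w)
        self._xr = xr
        y = np.empty((b, self.c_out, 2 * h, 2 * w),
                     dtype=np.result_type(x, self.params["W"]))
        for i in range(2):
            for j in range(2):
                y[:, :, i::2, j::2] = np.matmul(
                    self.params["W"][:, :, i, j].T, xr).reshape(b, self.c_out,
                                                                h, w)
        return y + self.params["b"][None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xr = self._xr
        b, c, hw = xr.shape
        h = grad.shape[2] // 2
        w = grad.shape[3] // 2
        dx = np.zeros_like(xr)
        for i in range(2):
            for j in range(2):
                g = np.ascontiguousarray(
                    grad[:, :, i::2, j::2]).reshape(b, self.c_out, hw)
                self.grads["W"][:, :, i, j] += \
                    np.matmul(xr, g.transpose(0, 2, 1)).sum(axis=0)
                dx += np.matmul(self.params["W"][:, :, i, j], g)
        self.grads["b"] += grad.sum(axis=(0, 2, 3))
        return dx.reshape(b, c, h, w)


def softmax_channels(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax across axis 1 (class channels)."""
    zm = z - z.max(axis=1, keepdims=True)
    e = np.exp(zm)
    return e / e.sum(axis=1, keepdims=True)


class SGDMomentum:
    """Classic SGD with momentum over a list of layers."""

    def __init__(self, layers: list[Layer], lr: float, momentum: float = 0.9):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.momentum = momentum
        self._vel = [{k: np.zeros_like(v) for k, v in l.params.items()}
                     for l in self.layers]

    def zero_grad(self) -> None:
        for layer in self.layers:
            for g in layer.grads.values():
                g[...] = 0.0

    def step(self) -> None:
        for layer, vel in zip(self.layers, self._vel):
            for k in layer.params:
                vel[k] = self.momentum * vel[k] - self.lr * layer.grads[k]
                layer.params[k] += vel[k]
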