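"""Reverse-mode differentiable layers on numpy arrays.

This is the package's autodiff core: a small set of neural-network layers
(convolutions, batch normalization, pooling, pointwise nonlinearities) with
hand-derived backward passes, plus the Adam optimizer.  Layers operate on
``(N, C, H, W)`` float arrays and cache what their backward pass needs.
Gradient correctness is pinned down by finite-difference tests rather than
by construction, so every backward formula here is covered by the test
suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "Tanh",
    "MaxPool2d",
    "Sequential",
    "Adam",
]


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: forward caches, backward consumes the cache once."""

    training: bool = True

    def params(self) -> list[Param]:
        return []

    def train(self) -> None:
        self.training = True

    def eval(self) -> None:
        self.training = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _uniform_fan_in(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Conv2d(Module):
    """k x k convolution, zero-padded to preserve spatial shape (odd k)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float64):
        if kernel % 2 != 1:
            raise ValueError("Conv2d supports odd kernel sizes only")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        self.weight = Param(_uniform_fan_in(rng, (out_ch, in_ch, kernel, kernel),
                                            fan_in, dtype), "conv.weight")
        self.bias = Param(_uniform_fan_in(rng, (out_ch,), fan_in, dtype), "conv.bias")
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x):
        k = self.kernel
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        # (N, C, H, W, k, k) sliding windows over the padded input
        sw = sliding_window_view(xp, (k, k), axis=(2, 3))
        y = np.tensordot(sw, self.weight.value, axes=([1, 4, 5], [1, 2, 3]))
        y = np.moveaxis(y, 3, 1) + self.bias.value[None, :, None, None]
        self._cache = sw, x.shape
        return np.ascontiguousarray(y)

    def backward(self, dy):
        sw, x_shape = self._cache
        self._cache = None
        k = self.kernel
        p = k // 2
        n, c, h, w = x_shape
        self.weight.grad += np.tensordot(dy, sw, axes=([0, 2, 3], [0, 2, 3]))
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        # gradient w.r.t. the sliding windows, scattered back onto the input
        dsw = np.tensordot(np.moveaxis(dy, 1, 3), self.weight.value, axes=([3], [0]))
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + h, dj:dj + w] += np.moveaxis(dsw[..., di, dj], 3, 1)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ConvTranspose2d(Module):
    """2 x 2 transposed convolution with stride 2 (non-overlapping upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Param(_uniform_fan_in(rng, (in_ch, out_ch, 2, 2), in_ch, dtype),
                            "convT.weight")
        self.bias = Param(_uniform_fan_in(rng, (out_ch,), in_ch, dtype), "convT.bias")
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x):
        n, c, h, w = x.shape
        t = np.tensordot(x, self.weight.value, axes=([1], [0]))  # (N,H,W,O,2,2)
        y = np.moveaxis(t, 3, 1)                                  # (N,O,H,W,2,2)
        y = y.transpose(0, 1, 2, 4, 3, 5).reshape(n, self.out_ch, 2 * h, 2 * w)
        self._cache = x
        return np.ascontiguousarray(y + self.bias.value[None, :, None, None])

    def backward(self, dy):
        x = self._cache
        self._cache = None
        n, c, h, w = x.shape
        dt = dy.reshape(n, self.out_ch, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        self.weight.grad += np.tensordot(x, dt, axes=([0, 2, 3], [0, 1, 2]))
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        dx = np.tensordot(dt, self.weight.value, axes=([3, 4, 5], [1, 2, 3]))
        return np.ascontiguousarray(np.moveaxis(dx, 3, 1))


class BatchNorm2d(Module):
    """Per-channel normalization over (N, H, W); batch stats while training,
    running stats at evaluation time."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float64):
        self.gamma = Param(np.ones(channels, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.eps, self.momentum = eps, momentum
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        if self.training:
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
        self._cache = xhat, inv, x.shape
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, dy):
        xhat, inv, x_shape = self._cache
        self._cache = None
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None] * inv[None, :, None, None]
        if not self.training:
            return dy * g
        m = x_shape[0] * x_shape[2] * x_shape[3]
        dy_sum = dy.sum(axis=(0, 2, 3))[None, :, None, None]
        dyx_sum = (dy * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return g * (dy - dy_sum / m - xhat * dyx_sum / m)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Tanh(Module):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y ** 2)


class MaxPool2d(Module):
    """2 x 2 max pooling, stride 2; spatial sides must be even."""

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d needs even sides, got {h}x{w}")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = idx, x.shape
        return y

    def backward(self, dy):
        idx, x_shape = self._cache
        self._cache = None
        n, c, h, w = x_shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
        dblk = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dblk.reshape(n, c, h, w)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def train(self):
        for layer in self.layers:
            layer.train()
        self.training = True

    def eval(self):
        for layer in self.layers:
            layer.eval()
        self.training = False

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adaptive-moment estimation over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
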