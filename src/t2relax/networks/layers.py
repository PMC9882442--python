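"""Minimal neural-network layers on numpy with explicit backpropagation.

Each layer caches what its backward pass needs during ``forward`` and
returns the gradient with respect to its input from ``backward``.  Shapes
follow the channels-first convention for images: ``(B, C, H, W)``; dense
layers use ``(B, features)``.  All parameters are float64 for bitwise
reproducibility under a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "ReLU",
    "PReLU",
    "Conv2d",
    "BatchNorm2d",
    "Upsample2x",
    "Sequential",
]


class Parameter:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: parameter collection plus train/eval mode switching."""

    training: bool = True

    def params(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.set_training(flag)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(flag)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def buffers(self) -> list[np.ndarray]:
        """Non-learnable state (e.g. batch-norm running statistics)."""
        out: list[np.ndarray] = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.buffers())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.buffers())
        return out

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, arrays) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError("state length mismatch")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError("state shape mismatch")
            p.value[...] = a

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Parameter(_uniform_init(rng, (n_out, n_in), n_in))
        self.bias = Parameter(_uniform_init(rng, (n_out,), n_in))
        self._x: np.ndarray | None = None

    def forward(self, x):
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class PReLU(Module):
    """Parametric ReLU with a single learnable negative slope (init 0.25)."""

    def __init__(self):
        self.alpha = Parameter(np.array(0.25))

    def forward(self, x):
        self._x = x
        self._neg = x < 0
        return np.where(self._neg, self.alpha.value * x, x)

    def backward(self, grad):
        self.alpha.grad += np.sum(grad * self._x * self._neg)
        return np.where(self._neg, self.alpha.value * grad, grad)


class Conv2d(Module):
    """2D convolution (cross-correlation) via im2col.

    Supports square kernels with ``padding = kernel // 2`` and integer
    stride; output spatial size is ``ceil(H / stride)`` for kernel 3 /
    padding 1 and ``H / stride`` exactly for the sizes used here (powers
    of two).
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
    ):
        fan_in = c_in * kernel * kernel
        self.weight = Parameter(_uniform_init(rng, (c_out, fan_in), fan_in))
        self.bias = Parameter(_uniform_init(rng, (c_out,), fan_in))
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride = kernel, stride
        self.pad = kernel // 2

    def forward(self, x):
        b, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        windows = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (B, C, Ho, Wo, k, k) -> (B, Ho, Wo, C, k, k) -> (B*Ho*Wo, C*k*k)
        b_, _, ho, wo = windows.shape[:4]
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * k * k)
        self._cols = cols
        self._x_shape = x.shape
        self._out_hw = (ho, wo)
        y = cols @ self.weight.value.T + self.bias.value
        return y.reshape(b, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        b, _, ho, wo = grad.shape
        k, s, p = self.kernel, self.stride, self.pad
        gflat = grad.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.weight.grad += gflat.T @ self._cols
        self.bias.grad += gflat.sum(axis=0)
        gcols = (gflat @ self.weight.value).reshape(b, ho, wo, self.c_in, k, k)
        gcols = gcols.transpose(0, 3, 1, 2, 4, 5)  # (B, C, Ho, Wo, k, k)
        _, _, h, w = self._x_shape
        dxp = np.zeros((b, self.c_in, h + 2 * p, w + 2 * p))
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + ho * s : s, dj : dj + wo * s : s] += gcols[
                    :, :, :, :, di, dj
                ]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Module):
    """Per-channel batch normalization over (B, H, W) with running stats."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_channels))
        self.beta = Parameter(np.zeros(n_channels))
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.momentum = momentum
        self.eps = eps

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            n = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * n / max(n - 1, 1)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._xhat, self._invstd = xhat, invstd
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, grad):
        xhat, invstd = self._xhat, self._invstd
        axes = (0, 2, 3)
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += np.sum(grad * xhat, axis=axes)
        self.beta.grad += np.sum(grad, axis=axes)
        g = grad * self.gamma.value[None, :, None, None]
        if not self.training:
            return g * invstd[None, :, None, None]
        gsum = g.sum(axis=axes, keepdims=True)
        gx_sum = (g * xhat).sum(axis=axes, keepdims=True)
        return (
            (g - gsum / n - xhat * gx_sum / n) * invstd[None, :, None, None]
        )


class Upsample2x(Module):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        b, c, h, w = grad.shape
        return grad.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
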