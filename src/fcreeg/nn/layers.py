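"""Minimal feed-forward CNN layers with explicit backprop.

Convolution uses im2col + matmul; every layer implements forward(x) and
backward(grad) and exposes its parameters as Param objects so a single
optimizer can update any composed network.  Arrays are NCHW float32 by
default (float64 supported, used by the numerical gradient checks).
"""
from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = data
        self.grad = np.zeros_like(data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: parameter iteration and train/eval mode switching."""

    training: bool = True

    def parameters(self) -> list[Param]:
        params: list[Param] = []
        for v in vars(self).values():
            if isinstance(v, Param):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for v in vars(self).values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N, C, H, W) -> columns (N, C*kh*kw, Ho*Wo) plus output dims."""
    n, c, h, w = x.shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride), writeable=False)
    return view.reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    """Scatter-add columns back to the (padded) input; inverse of _im2col."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                cols[:, :, i, j]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


class Conv2d(Module):
    """2-D convolution (cross-correlation); bias off when followed by BN."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int = 0, bias: bool = False, *, rng: np.random.Generator,
                 dtype=np.float32):
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.pad = stride, pad
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.weight = Param(w.astype(dtype), "conv.weight")
        self.bias = Param(np.zeros(cout, dtype=dtype), "conv.bias") if bias else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        cols, ho, wo = _im2col(x, self.k, self.k, self.stride, self.pad)
        self._cols = cols
        wmat = self.weight.data.reshape(self.cout, -1)
        out = np.einsum("of,nfl->nol", wmat, cols, optimize=True)
        if self.bias is not None:
            out += self.bias.data[None, :, None]
        return out.reshape(x.shape[0], self.cout, ho, wo)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n = grad.shape[0]
        gmat = grad.reshape(n, self.cout, -1)
        self.weight.grad += np.einsum(
            "nol,nfl->of", gmat, self._cols, optimize=True
        ).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += gmat.sum(axis=(0, 2))
        wmat = self.weight.data.reshape(self.cout, -1)
        dcols = np.einsum("of,nol->nfl", wmat, gmat, optimize=True)
        self._cols = None
        return _col2im(dcols, self._x_shape, self.k, self.k, self.stride, self.pad)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(c, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(c, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        return (self.gamma.data[None, :, None, None] * self._xhat
                + self.beta.data[None, :, None, None])

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        m = n * h * w
        self.gamma.grad += (grad * self._xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        if not self.training:
            return grad * (self.gamma.data / self._std)[None, :, None, None]
        g = grad * self.gamma.data[None, :, None, None]
        sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (g * self._xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (g - sum_g / m - self._xhat * sum_gx / m) / \
            self._std[None, :, None, None]
        self._xhat = None
        return dx


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class MaxPool2d(Module):
    def __init__(self, k: int, stride: int, pad: int = 0):
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        n, c, _, _ = x.shape
        xr = x.reshape(n * c, 1, *x.shape[2:])
        if self.pad:
            xr = np.pad(xr, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2),
                        constant_values=-np.inf)
        cols, ho, wo = _im2col(xr, self.k, self.k, self.stride, 0)
        cols = cols.reshape(n * c, self.k * self.k, ho * wo)
        self._argmax = cols.argmax(axis=1)
        self._dims = (ho, wo)
        out = np.take_along_axis(cols, self._argmax[:, None, :], axis=1)
        return out.reshape(n, c, ho, wo)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        ho, wo = self._dims
        gcols = np.zeros((n * c, self.k * self.k, ho * wo), dtype=grad.dtype)
        np.put_along_axis(gcols, self._argmax[:, None, :],
                          grad.reshape(n * c, 1, ho * wo), axis=1)
        padded_shape = (n * c, 1, h + 2 * self.pad, w + 2 * self.pad)
        dx = _col2im(gcols.reshape(n * c, self.k * self.k, ho * wo),
                     (n * c, 1, h + 2 * self.pad, w + 2 * self.pad),
                     self.k, self.k, self.stride, 0)
        if self.pad:
            dx = dx[:, :, self.pad:-self.pad, self.pad:-self.pad]
        self._argmax = None
        return dx.reshape(n, c, h, w)


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._dims = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        h, w = self._dims
        return np.broadcast_to(grad[:, :, None, None] / (h * w),
                               (*grad.shape, h, w)).copy()


class Linear(Module):
    def __init__(self, fin: int, fout: int, *, rng: np.random.Generator,
                 dtype=np.float32):
        w = rng.normal(0.0, np.sqrt(2.0 / fin), size=(fin, fout))
        self.weight = Param(w.astype(dtype), "fc.weight")
        self.bias = Param(np.zeros(fout, dtype=dtype), "fc.bias")

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.data + self.bias.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        out = grad @ self.weight.data.T
        self._x = None
        return out


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
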