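"""Minimal dense-tensor neural-network layers with explicit backpropagation.

Layers operate on ``(N, C, *spatial)`` float64 arrays with 2 or 3 spatial
dimensions. Convolutions are evaluated as im2col + BLAS matrix products; the
gradient with respect to the input is computed as a stride-dilated transposed
convolution through the same im2col path, so every heavy operation is a
matmul. All layers are deterministic; randomness enters only through
parameter initialization and the training loop.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Module",
    "Conv",
    "BatchNorm",
    "ReLU",
    "MaxPool",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
]


class Param:
    """A learnable tensor with an accumulated gradient.

    ``decay`` marks parameters included in the L2 regularization term
    (convolution/linear weights but not biases or batch-norm scales).
    """

    __slots__ = ("value", "grad", "decay", "name")

    def __init__(self, value: np.ndarray, decay: bool = True, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.decay = decay
        self.name = name


class Module:
    """Base class: tracks child modules/params, training mode, and backprop."""

    def __init__(self):
        object.__setattr__(self, "_children", [])
        object.__setattr__(self, "_params", [])
        object.__setattr__(self, "training", True)

    def __setattr__(self, key, value):
        if isinstance(value, Module):
            self._children.append(value)
        elif isinstance(value, Param):
            self._params.append(value)
        object.__setattr__(self, key, value)

    def parameters(self):
        yield from self._params
        for child in self._children:
            yield from child.parameters()

    def set_training(self, flag: bool) -> None:
        object.__setattr__(self, "training", flag)
        for child in self._children:
            child.set_training(flag)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


def _tuple(v, dim):
    return tuple(v) if isinstance(v, (tuple, list)) else (v,) * dim


def _im2col(x: np.ndarray, ks, stride, pad):
    """Return ``(patches, out_spatial)`` with patches ``(N, P_out, C*prod(ks))``."""
    dim = x.ndim - 2
    n, c = x.shape[:2]
    xp = np.pad(x, ((0, 0), (0, 0)) + tuple((p, p) for p in pad))
    win = sliding_window_view(xp, ks, axis=tuple(range(2, 2 + dim)))
    win = win[(slice(None), slice(None)) + tuple(slice(None, None, s) for s in stride)]
    out_spatial = win.shape[2 : 2 + dim]
    perm = (0,) + tuple(range(2, 2 + dim)) + (1,) + tuple(range(2 + dim, 2 + 2 * dim))
    patches = win.transpose(perm).reshape(n, int(np.prod(out_spatial)), c * int(np.prod(ks)))
    return np.ascontiguousarray(patches), out_spatial


class Conv(Module):
    """N-dimensional convolution (cross-correlation) with 'same'-style padding."""

    def __init__(self, in_channels, out_channels, kernel_size, dim, stride=1,
                 padding=None, bias=True):
        super().__init__()
        self.dim = dim
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.ks = _tuple(kernel_size, dim)
        self.stride = _tuple(stride, dim)
        self.pad = _tuple(padding, dim) if padding is not None else tuple(k // 2 for k in self.ks)
        fan_in = in_channels * int(np.prod(self.ks))
        self.weight = Param(
            np.zeros((out_channels, in_channels) + self.ks), decay=True, name="conv.weight"
        )
        self.bias = Param(np.zeros(out_channels), decay=False, name="conv.bias") if bias else None
        self.fan_in = fan_in
        self._cache = None

    def forward(self, x):
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {x.shape[1]}")
        patches, out_spatial = _im2col(x, self.ks, self.stride, self.pad)
        wf = self.weight.value.reshape(self.out_channels, -1)
        out = patches @ wf.T
        if self.bias is not None:
            out += self.bias.value
        self._cache = (patches, x.shape, out_spatial)
        n = x.shape[0]
        return np.ascontiguousarray(
            np.moveaxis(out.reshape((n,) + out_spatial + (self.out_channels,)), -1, 1)
        )

    def backward(self, grad):
        patches, in_shape, out_spatial = self._cache
        n = in_shape[0]
        gflat = np.moveaxis(grad, 1, -1).reshape(n, -1, self.out_channels)
        self.weight.grad += np.tensordot(gflat, patches, axes=([0, 1], [0, 1])).reshape(
            self.weight.value.shape
        )
        if self.bias is not None:
            self.bias.grad += gflat.sum(axis=(0, 1))
        return self._input_grad(grad, in_shape, out_spatial)

    def _input_grad(self, grad, in_shape, out_spatial):
        """Transposed convolution: dilate by stride, full-correlate flipped kernel."""
        dim = self.dim
        spatial_in = in_shape[2:]
        padded_in = tuple(s + 2 * p for s, p in zip(spatial_in, self.pad))
        # Dilate the output gradient by the stride, then append zeros so the
        # full correlation reconstructs the padded input extent exactly.
        dil = tuple((o - 1) * s + 1 for o, s in zip(out_spatial, self.stride))
        tail = tuple(pi - (d + k - 1) for pi, d, k in zip(padded_in, dil, self.ks))
        gd = np.zeros((in_shape[0], self.out_channels) + dil)
        gd[(slice(None), slice(None)) + tuple(slice(None, None, s) for s in self.stride)] = grad
        w_t = self.weight.value
        for ax in range(2, 2 + dim):
            w_t = np.flip(w_t, axis=ax)
        w_t = np.swapaxes(w_t, 0, 1)  # (C_in, C_out, *ks)
        pads = tuple((k - 1, k - 1 + t) for k, t in zip(self.ks, tail))
        gd = np.pad(gd, ((0, 0), (0, 0)) + pads)
        patches, _ = _im2col(gd, self.ks, (1,) * dim, (0,) * dim)
        gx = patches @ w_t.reshape(self.in_channels, -1).T
        gx = np.moveaxis(gx.reshape((in_shape[0],) + padded_in + (self.in_channels,)), -1, 1)
        crop = (slice(None), slice(None)) + tuple(
            slice(p, p + s) for p, s in zip(self.pad, spatial_in)
        )
        return np.ascontiguousarray(gx[crop])


class BatchNorm(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels), decay=False, name="bn.gamma")
        self.beta = Param(np.zeros(channels), decay=False, name="bn.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def _bshape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x):
        axes = (0,) + tuple(range(2, x.ndim))
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        bs = self._bshape(x)
        std = np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(bs)) / std.reshape(bs)
        self._cache = (xhat, std, axes)
        return self.gamma.value.reshape(bs) * xhat + self.beta.value.reshape(bs)

    def backward(self, grad):
        xhat, std, axes = self._cache
        bs = self._bshape(xhat)
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        scale = self.gamma.value.reshape(bs) / std.reshape(bs)
        if not self.training:
            return grad * scale
        m = float(np.prod([xhat.shape[a] for a in axes]))
        g_mean = grad.mean(axis=axes).reshape(bs)
        gx_mean = (grad * xhat).sum(axis=axes).reshape(bs) / m
        return scale * (grad - g_mean - xhat * gx_mean)


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool(Module):
    """Non-overlapping max pooling; odd extents are padded with -inf."""

    def __init__(self, kernel_size):
        super().__init__()
        self.ks = tuple(kernel_size)
        self._cache = None

    def forward(self, x):
        dim = len(self.ks)
        spatial = x.shape[2:]
        padded = tuple(-(-s // k) * k for s, k in zip(spatial, self.ks))
        if padded != spatial:
            pads = ((0, 0), (0, 0)) + tuple(
                (0, p - s) for s, p in zip(spatial, padded)
            )
            x = np.pad(x, pads, constant_values=-np.inf)
        n, c = x.shape[:2]
        out = tuple(p // k for p, k in zip(padded, self.ks))
        shape = (n, c) + tuple(v for o, k in zip(out, self.ks) for v in (o, k))
        xr = x.reshape(shape)
        # bring the window axes last: (N, C, o1..od, k1..kd)
        perm = (0, 1) + tuple(2 + 2 * i for i in range(dim)) + tuple(3 + 2 * i for i in range(dim))
        xr = xr.transpose(perm).reshape((n, c) + out + (int(np.prod(self.ks)),))
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape, spatial, out, perm)
        return y

    def backward(self, grad):
        idx, padded_shape, spatial, out, perm = self._cache
        n, c = padded_shape[:2]
        z = np.zeros((n, c) + out + (int(np.prod(self.ks)),))
        np.put_along_axis(z, idx[..., None], grad[..., None], axis=-1)
        dim = len(self.ks)
        z = z.reshape((n, c) + out + self.ks)
        inv = np.argsort(perm)
        z = z.transpose(inv).reshape(padded_shape)
        crop = (slice(None), slice(None)) + tuple(slice(0, s) for s in spatial)
        return np.ascontiguousarray(z[crop])


class GlobalAvgPool(Module):
    """Adaptive average pooling to one value per channel: (N, C, *S) -> (N, C)."""

    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, grad):
        shape = self._shape
        p = int(np.prod(shape[2:]))
        g = (grad / p).reshape(shape[:2] + (1,) * (len(shape) - 2))
        return np.broadcast_to(g, shape).copy()


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.fan_in = in_features
        self.weight = Param(np.zeros((out_features, in_features)), decay=True, name="linear.weight")
        self.bias = Param(np.zeros(out_features), decay=False, name="linear.bias") if bias else None
        self._x = None

    def forward(self, x):
        self._x = x
        out = x @ self.weight.value.T
        if self.bias is not None:
            out += self.bias.value
        return out

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.layers = list(modules)
        for i, m in enumerate(modules):
            setattr(self, f"m{i}", m)

    def forward(self, x):
        for m in self.layers:
            x = m(x)
        return x

    def backward(self, grad):
        for m in reversed(self.layers):
            grad = m.backward(grad)
        return grad


def kaiming_normal_(param: Param, fan_in: int, rng: np.random.Generator) -> None:
    """He initialization: zero-mean normal with variance 2 / fan_in."""
    std = math.sqrt(2.0 / fan_in)
    param.value[...] = rng.normal(0.0, std, size=param.value.shape)
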