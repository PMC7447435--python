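"""Minimal N-dimensional CNN layers with explicit forward/backward passes.

The boundary-prediction networks used here are small (two or three levels,
a handful of feature maps) and run on CPU, so the layers are implemented
directly on numpy: convolutions as im2col + matmul, pooling/upsampling as
reshapes, and hand-derived backward passes.  Tensors are laid out as
``(batch, channels, *spatial)`` with 2 or 3 spatial dimensions.

Every layer exposes ``forward(x, training)``, ``backward(grad)`` and a
``params`` list of :class:`Param`; gradient correctness is pinned down by
finite-difference tests.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32  # set to float64 for high-precision gradient checks

__all__ = [
    "Param",
    "Layer",
    "Conv",
    "GroupNorm",
    "BatchNorm",
    "ReLU",
    "MaxPool",
    "Upsample",
    "sigmoid",
]


class Param:
    """A learnable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # whether L2 weight decay applies


class Layer:
    params: list[Param]

    def __init__(self):
        self.params = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Conv(Layer):
    """Same-padded convolution with odd kernel size and stride 1.

    Weights are He-initialised; the kernel is stored flattened as
    ``(in_channels * k^d, out_channels)`` for the im2col matmul.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        ndim: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd for same convolutions")
        self.cin, self.cout, self.k, self.ndim = in_channels, out_channels, kernel_size, ndim
        fan_in = in_channels * kernel_size**ndim
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_channels))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_channels), decay=False)
        self.params = [self.weight, self.bias]
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        pad = [(0, 0), (0, 0)] + [(p, p)] * self.ndim
        xp = np.pad(x, pad)
        axes = tuple(range(2, 2 + self.ndim))
        view = sliding_window_view(xp, (self.k,) * self.ndim, axis=axes)
        # (N, C, *spatial, *k) -> (N, *spatial, C, *k) -> (N*S, C*k^d)
        n = x.shape[0]
        spatial = x.shape[2:]
        perm = (0,) + tuple(range(2, 2 + self.ndim)) + (1,) + tuple(
            range(2 + self.ndim, 2 + 2 * self.ndim)
        )
        cols = np.ascontiguousarray(view.transpose(perm), dtype=DTYPE)
        return cols.reshape(n * int(np.prod(spatial)), -1)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        cols = self._im2col(x)
        out = cols @ self.weight.value + self.bias.value
        self._cols = cols if training else None
        self._shape = x.shape
        n, spatial = x.shape[0], x.shape[2:]
        out = out.reshape((n,) + spatial + (self.cout,))
        return np.moveaxis(out, -1, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._cols is not None, "forward(training=True) required before backward"
        n, spatial = self._shape[0], self._shape[2:]
        g = np.moveaxis(grad, 1, -1).reshape(-1, self.cout).astype(DTYPE)
        self.weight.grad += self._cols.T @ g
        self.bias.grad += g.sum(axis=0)
        # dx: correlate grad with the spatially flipped, channel-transposed kernel
        w = self.weight.value.reshape((self.cin,) + (self.k,) * self.ndim + (self.cout,))
        w_flip = w[(slice(None),) + (slice(None, None, -1),) * self.ndim]
        # reorder (cin, *k, cout) -> (cout, *k, cin) to match im2col column layout
        w_back = w_flip.transpose(
            (self.ndim + 1,) + tuple(range(1, self.ndim + 1)) + (0,)
        ).reshape(self.cout * self.k**self.ndim, self.cin)
        gconv = Conv.__new__(Conv)
        # reuse _im2col machinery on the gradient tensor
        gconv.k, gconv.ndim = self.k, self.ndim
        cols_g = Conv._im2col(gconv, grad.astype(DTYPE))
        dx = cols_g @ w_back
        dx = dx.reshape((n,) + spatial + (self.cin,))
        self._cols = None
        return np.moveaxis(dx, -1, 1)


class _NormBase(Layer):
    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.gamma = Param(np.ones(channels), decay=False)
        self.beta = Param(np.zeros(channels), decay=False)
        self.params = [self.gamma, self.beta]

    @staticmethod
    def _normalize_backward(dxhat, xhat, inv_std, axes):
        m = np.prod([xhat.shape[a] for a in axes])
        s1 = dxhat.sum(axis=axes, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        return (dxhat - s1 / m - xhat * s2 / m) * inv_std


class GroupNorm(_NormBase):
    """Group normalisation over (channel-group, spatial) per sample."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        groups = min(groups, channels)
        while channels % groups != 0:
            groups -= 1
        super().__init__(channels, eps)
        self.groups = groups

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c = x.shape[:2]
        spatial = x.shape[2:]
        xg = x.reshape(n, self.groups, c // self.groups, *spatial).astype(DTYPE)
        axes = tuple(range(2, xg.ndim))
        mu = xg.mean(axis=axes, keepdims=True)
        var = xg.var(axis=axes, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (xg - mu) * inv_std
        if training:
            self._cache = (xhat, inv_std, x.shape, axes)
        gshape = (1, c) + (1,) * len(spatial)
        return xhat.reshape(x.shape) * self.gamma.value.reshape(gshape) + self.beta.value.reshape(
            gshape
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape, axes = self._cache
        n, c = shape[:2]
        spatial = shape[2:]
        red = tuple([0] + list(range(2, len(shape))))
        xh_full = xhat.reshape(shape)
        self.gamma.grad += (grad * xh_full).sum(axis=red)
        self.beta.grad += grad.sum(axis=red)
        gshape = (1, c) + (1,) * len(spatial)
        dxhat = (grad * self.gamma.value.reshape(gshape)).reshape(xhat.shape)
        dx = self._normalize_backward(dxhat, xhat, inv_std, axes)
        return dx.reshape(shape)


class BatchNorm(_NormBase):
    """Batch normalisation over (batch, spatial) per channel, with running
    statistics for inference."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__(channels, eps)
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        c = x.shape[1]
        gshape = (1, c) + (1,) * (x.ndim - 2)
        axes = tuple([0] + list(range(2, x.ndim)))
        if training:
            mu = x.mean(axis=axes, keepdims=True)
            var = x.var(axis=axes, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.ravel()
            ).astype(DTYPE)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.ravel()
            ).astype(DTYPE)
        else:
            mu = self.running_mean.reshape(gshape)
            var = self.running_var.reshape(gshape)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        if training:
            self._cache = (xhat, inv_std, axes)
        return xhat * self.gamma.value.reshape(gshape) + self.beta.value.reshape(gshape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes = self._cache
        c = grad.shape[1]
        gshape = (1, c) + (1,) * (grad.ndim - 2)
        red = axes
        self.gamma.grad += (grad * xhat).sum(axis=red)
        self.beta.grad += grad.sum(axis=red)
        dxhat = grad * self.gamma.value.reshape(gshape)
        s1 = dxhat.sum(axis=axes, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        m = np.prod([grad.shape[a] for a in axes])
        return (dxhat - s1 / m - xhat * s2 / m) * inv_std


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool(Layer):
    """2× max pooling over every spatial axis (requires even extents)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c = x.shape[:2]
        spatial = x.shape[2:]
        if any(s % 2 for s in spatial):
            raise ValueError(
                f"spatial shape {spatial} not divisible by 2; pad the input to a "
                "multiple of 2^(depth-1) before the forward pass"
            )
        nd = len(spatial)
        shape = (n, c) + sum(((s // 2, 2) for s in spatial), ())
        xr = x.reshape(shape)
        # bring the window axes (3, 5, ...) to the back
        perm = (0, 1) + tuple(2 + 2 * i for i in range(nd)) + tuple(3 + 2 * i for i in range(nd))
        xr = xr.transpose(perm).reshape(n, c, *[s // 2 for s in spatial], 2**nd)
        out = xr.max(axis=-1)
        if training:
            self._argmax = xr.argmax(axis=-1)
            self._in_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c = self._in_shape[:2]
        spatial = self._in_shape[2:]
        nd = len(spatial)
        half = [s // 2 for s in spatial]
        win = np.zeros(grad.shape + (2**nd,), dtype=grad.dtype)
        np.put_along_axis(win, self._argmax[..., None], grad[..., None], axis=-1)
        win = win.reshape((n, c) + tuple(half) + (2,) * nd)
        inv = np.argsort((0, 1) + tuple(2 + 2 * i for i in range(nd)) + tuple(3 + 2 * i for i in range(nd)))
        win = win.transpose(tuple(inv))
        return win.reshape(self._in_shape)


class Upsample(Layer):
    """2× nearest-neighbour upsampling over every spatial axis."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = x
        for axis in range(2, x.ndim):
            out = np.repeat(out, 2, axis=axis)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c = grad.shape[:2]
        spatial = grad.shape[2:]
        nd = len(spatial)
        shape = (n, c) + sum(((s // 2, 2) for s in spatial), ())
        g = grad.reshape(shape)
        for i in range(nd):
            g = g.sum(axis=3 + i)  # window axes collapse left to right
        return g
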