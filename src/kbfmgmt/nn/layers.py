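"""Minimal CNN layer zoo with explicit forward/backward passes.

Only what the methylation classifier needs: depthwise and pointwise
convolutions (together a depthwise-separable convolution), batch
normalization, ReLU, flatten and dense layers.  All arithmetic is float32
NumPy; every layer caches what its backward pass requires, so a
``forward(train=True)`` must precede each ``backward``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import List

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "DepthwiseConv",
    "PointwiseConv",
    "BatchNorm",
    "ReLU",
    "Flatten",
    "Dense",
]


@dataclass
class Param:
    """A trainable tensor and its accumulated gradient."""

    name: str
    value: np.ndarray
    grad: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=np.float32)
        if self.grad is None:
            self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class DepthwiseConv(Layer):
    """Per-channel spatial convolution, kernel 3, stride 2, padding 1.

    Channel-preserving: each input channel is convolved with its own
    ``3 ** dims`` kernel.  No bias (batch normalization follows in the
    block).  Output side for input side ``n`` is ``floor((n - 1) / 2) + 1``.
    """

    def __init__(self, channels: int, dims: int, rng: np.random.Generator):
        self.channels = channels
        self.dims = dims
        fan_in = 3 ** dims
        self.w = Param(
            "depthwise.w",
            rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(channels,) + (3,) * dims),
        )
        self._cache = None

    def params(self) -> List[Param]:
        return [self.w]

    @staticmethod
    def out_side(n: int) -> int:
        return (n + 2 * 1 - 3) // 2 + 1

    def _offset_slices(self, offs, out_shape):
        return tuple(
            slice(k, k + 2 * (o - 1) + 1, 2) for k, o in zip(offs, out_shape)
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 2 + self.dims or x.shape[1] != self.channels:
            raise ValueError("bad input shape for depthwise convolution")
        pad = [(0, 0), (0, 0)] + [(1, 1)] * self.dims
        xpad = np.pad(x, pad)
        out_shape = tuple(self.out_side(n) for n in x.shape[2:])
        y = np.zeros(x.shape[:2] + out_shape, dtype=np.float32)
        w = self.w.value
        bshape = (1, self.channels) + (1,) * self.dims
        for offs in itertools.product(range(3), repeat=self.dims):
            sl = (slice(None), slice(None)) + self._offset_slices(offs, out_shape)
            y += w[(slice(None),) + offs].reshape(bshape) * xpad[sl]
        if train:
            self._cache = (xpad, x.shape, out_shape)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xpad, x_shape, out_shape = self._cache
        w = self.w.value
        bshape = (1, self.channels) + (1,) * self.dims
        gxpad = np.zeros_like(xpad)
        red_axes = (0,) + tuple(range(2, 2 + self.dims))
        for offs in itertools.product(range(3), repeat=self.dims):
            sl = (slice(None), slice(None)) + self._offset_slices(offs, out_shape)
            self.w.grad[(slice(None),) + offs] += np.sum(gy * xpad[sl], axis=red_axes)
            gxpad[sl] += w[(slice(None),) + offs].reshape(bshape) * gy
        crop = (slice(None), slice(None)) + tuple(
            slice(1, 1 + n) for n in x_shape[2:]
        )
        return gxpad[crop]


class PointwiseConv(Layer):
    """1x1(x1) convolution across channels, stride 1, no padding, no bias."""

    def __init__(self, in_channels: int, out_channels: int, dims: int,
                 rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.dims = dims
        self.w = Param(
            "pointwise.w",
            rng.normal(0.0, np.sqrt(2.0 / in_channels),
                       size=(out_channels, in_channels)),
        )
        self._x = None

    def params(self) -> List[Param]:
        return [self.w]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.einsum("oc,bc...->bo...", self.w.value, x)
        if train:
            self._x = x
        return y.astype(np.float32, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        red = (0,) + tuple(range(2, gy.ndim))  # batch + spatial axes
        self.w.grad += np.tensordot(gy, self._x, axes=(red, red))
        return np.einsum("oc,bo...->bc...", self.w.value, gy).astype(
            np.float32, copy=False
        )


class BatchNorm(Layer):
    """Per-channel batch normalization with learnable affine parameters.

    Training normalises with batch statistics and updates exponential
    running estimates (momentum 0.1); evaluation uses the running estimates,
    so inference is deterministic and batch-size independent.
    """

    def __init__(self, channels: int, dims: int, *, eps: float = 1e-5,
                 momentum: float = 0.1):
        self.channels = channels
        self.dims = dims
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param("bn.gamma", np.ones(channels))
        self.beta = Param("bn.beta", np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def _cshape(self):
        return (1, self.channels) + (1,) * self.dims

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0,) + tuple(range(2, 2 + self.dims))
        cs = self._cshape()
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(cs)) * invstd.reshape(cs)
        if train:
            m = x.size // self.channels
            self._cache = (xhat, invstd, m, axes)
        return (self.gamma.value.reshape(cs) * xhat
                + self.beta.value.reshape(cs)).astype(np.float32, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, invstd, m, axes = self._cache
        cs = self._cshape()
        self.gamma.grad += np.sum(gy * xhat, axis=axes)
        self.beta.grad += np.sum(gy, axis=axes)
        g = self.gamma.value.reshape(cs)
        sum_gy = np.sum(gy, axis=axes).reshape(cs)
        sum_gy_xhat = np.sum(gy * xhat, axis=axes).reshape(cs)
        gx = (g * invstd.reshape(cs) / m) * (m * gy - sum_gy - xhat * sum_gy_xhat)
        return gx.astype(np.float32, copy=False)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer with bias."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        self.in_features = in_features
        self.out_features = out_features
        self.w = Param(
            "dense.w",
            rng.normal(0.0, np.sqrt(2.0 / in_features),
                       size=(out_features, in_features)),
        )
        self.b = Param("dense.b", np.zeros(out_features))
        self._x = None

    def params(self) -> List[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return (x @ self.w.value.T + self.b.value).astype(np.float32, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.w.grad += gy.T @ self._x
        self.b.grad += gy.sum(axis=0)
        return (gy @ self.w.value).astype(np.float32, copy=False)
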