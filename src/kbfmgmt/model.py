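"""The methylation classifier: a compact 2D/3D depthwise-separable CNN.

Seven convolutional blocks halve the spatial extent each (depthwise 3x3(x3)
convolution, stride 2, padding 1, channel-preserving; then a pointwise
1x1(x1) convolution that sets the channel count; batch normalization; ReLU),
doubling the channels after the first block (8, 16, ..., 512).  The feature
map is flattened into two fully connected layers producing a single binary
logit (methylation present vs absent).  The 2D and 3D variants share the
identical block schema and differ only in kernel dimensionality.

Depthwise-separable factorisation keeps the network tiny — well under a
million trainable scalars in either variant — which is the point: small
cohorts cannot support large models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .nn import (BatchNorm, Dense, DepthwiseConv, Flatten, PointwiseConv,
                 ReLU, Sequential)

__all__ = [
    "ClassifierSpec",
    "AugmentationConfig",
    "build_classifier",
    "count_parameters",
    "block_spatial_sizes",
    "describe",
    "rotate_plane",
    "augment",
]

_DEFAULT_CHANNELS = (8, 16, 32, 64, 128, 256, 512)


@dataclass
class ClassifierSpec:
    """Declarative description of the classifier architecture.

    ``dims`` selects the 2D (slice) or 3D (volume) variant; ``input_side``
    is the cubic/square input edge length the dense head is sized for.
    """

    dims: int = 3
    block_channels: Tuple[int, ...] = _DEFAULT_CHANNELS
    spatial_kernel: int = 3
    spatial_stride: int = 2
    spatial_padding: int = 1
    pointwise_kernel: int = 1
    pointwise_stride: int = 1
    pointwise_padding: int = 0
    fc_hidden: int = 64
    n_outputs: int = 1
    input_side: int = 192
    seed: int = 0

    def __post_init__(self) -> None:
        self.block_channels = tuple(int(c) for c in self.block_channels)
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if len(self.block_channels) != 7:
            raise ValueError("the classifier uses exactly seven blocks")
        for a, b in zip(self.block_channels, self.block_channels[1:]):
            if b != 2 * a:
                raise ValueError("channel counts must double between blocks")
        if (self.spatial_kernel, self.spatial_stride, self.spatial_padding) != (3, 2, 1):
            raise ValueError("spatial convolution is fixed at kernel 3, stride 2, padding 1")
        if (self.pointwise_kernel, self.pointwise_stride, self.pointwise_padding) != (1, 1, 0):
            raise ValueError("pointwise convolution is fixed at kernel 1, stride 1, padding 0")
        if self.input_side < 8:
            raise ValueError(
                "input side too small to survive 7 stride-2 blocks"
            )


@dataclass
class AugmentationConfig:
    """Random rotations and axis flips applied during training."""

    rotation_range: float = 15.0  # degrees, uniform in [-range, +range]
    flip_axes: Tuple[int, ...] = (0, 1)
    probability: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("probability must lie in [0, 1]")
        if self.rotation_range < 0:
            raise ValueError("rotation_range must be >= 0")


def block_spatial_sizes(input_side: int, n_blocks: int = 7) -> List[int]:
    """Spatial edge length after each stride-2 block.

    Per block the convolution size formula ``floor((n + 2*pad - k)/stride) + 1``
    with k=3, pad=1, stride=2 gives ``floor((n - 1)/2) + 1``.
    """
    sizes = []
    n = input_side
    for _ in range(n_blocks):
        n = (n + 2 * 1 - 3) // 2 + 1
        sizes.append(n)
    return sizes


def build_classifier(spec: ClassifierSpec) -> Sequential:
    """Instantiate the network described by ``spec`` with seeded He-normal
    initial weights.  Convolutions carry no bias (batch normalization
    follows immediately)."""
    rng = np.random.default_rng(spec.seed)
    layers: list = []
    in_ch = 1
    for out_ch in spec.block_channels:
        layers.append(DepthwiseConv(in_ch, spec.dims, rng))
        layers.append(PointwiseConv(in_ch, out_ch, spec.dims, rng))
        layers.append(BatchNorm(out_ch, spec.dims))
        layers.append(ReLU())
        in_ch = out_ch
    final_side = block_spatial_sizes(spec.input_side)[-1]
    flat = spec.block_channels[-1] * final_side ** spec.dims
    layers.append(Flatten())
    layers.append(Dense(flat, spec.fc_hidden, rng))
    layers.append(ReLU())
    layers.append(Dense(spec.fc_hidden, spec.n_outputs, rng))
    return Sequential(layers)


def count_parameters(model: Sequential) -> int:
    """Total number of trainable scalars in the network."""
    return sum(p.size for p in model.parameters())


def describe(spec: ClassifierSpec) -> List[Tuple[str, str, int]]:
    """Layer table: (layer name, output shape, trainable parameters)."""
    model = build_classifier(spec)
    sizes = block_spatial_sizes(spec.input_side)
    rows: List[Tuple[str, str, int]] = []
    block = 0
    side = spec.input_side
    ch = 1
    width = None  # set once the feature map is flattened
    for layer in model.layers:
        name = type(layer).__name__
        if isinstance(layer, DepthwiseConv):
            side = sizes[block]
            block += 1
        if isinstance(layer, PointwiseConv):
            ch = layer.out_channels
        if isinstance(layer, Flatten):
            width = ch * side ** spec.dims
            shape = f"({width},)"
        elif isinstance(layer, Dense):
            width = layer.out_features
            shape = f"({width},)"
        elif width is not None:
            shape = f"({width},)"
        else:
            shape = f"({ch}, " + ", ".join([str(side)] * spec.dims) + ")"
        rows.append((name, shape, sum(p.size for p in layer.params())))
    return rows


def rotate_plane(x: np.ndarray, angle: float) -> np.ndarray:
    """Rotate by ``angle`` degrees in the (row, column) plane, preserving
    shape (linear interpolation, zero fill outside)."""
    return ndimage.rotate(np.asarray(x, float), angle, axes=(0, 1),
                          reshape=False, order=1, mode="constant", cval=0.0)


def augment(x: np.ndarray, cfg: AugmentationConfig, seed: int) -> np.ndarray:
    """Seeded random rotation and axis flips; output shape equals input shape.

    The rotation acts in the (row, column) plane (``scipy.ndimage.rotate``
    with ``reshape=False``, linear interpolation); each configured axis is
    flipped independently.  Every transform fires with probability
    ``cfg.probability``; at probability 0 the input is returned unchanged.
    """
    x = np.asarray(x)
    rng = np.random.default_rng(seed)
    out = x
    if cfg.probability > 0 and cfg.rotation_range > 0 and rng.random() < cfg.probability:
        angle = rng.uniform(-cfg.rotation_range, cfg.rotation_range)
        out = rotate_plane(out, angle)
    for axis in cfg.flip_axes:
        if cfg.probability > 0 and rng.random() < cfg.probability:
            out = np.flip(out, axis=axis)
    return np.ascontiguousarray(out) if out is not x else x
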