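"""Attribution maps for the methylation classifier.

Two complementary views of what drives a prediction:

* **Integrated gradients** — the input-to-baseline path integral of the
  logit's gradient, approximated by a Riemann right sum; satisfies the
  completeness property (attributions sum to ``F(x) - F(baseline)``) in the
  limit of many steps.
* **Occlusion** — slides a window over the input, replaces its content by
  the baseline value and records the output drop; a perturbation-based
  method needing no gradients.

Both operate on the raw logit (not the sigmoid) for gradient stability, and
use a zero baseline by default — the background value of the ROI-masked
inputs the classifier sees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .nn import Sequential

__all__ = [
    "AttributionMap",
    "integrated_gradients",
    "occlusion_map",
    "summarize_slice",
]


@dataclass
class AttributionMap:
    """Signed per-voxel importance scores, same shape as the input."""

    grid: np.ndarray
    method: str  # {integrated_gradients, occlusion}
    baseline: float = 0.0
    steps: Optional[int] = None
    window: Optional[Tuple[int, ...]] = None
    stride: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("attribution map contains non-finite values")


def _logit(model: Sequential, x: np.ndarray) -> float:
    return float(model.forward(x[None, None], train=False).reshape(-1)[0])


def integrated_gradients(model: Sequential, x: np.ndarray,
                         baseline: float = 0.0,
                         steps: int = 64) -> AttributionMap:
    """Path-integrated gradient attribution of the logit.

    ``attr_i = (x_i - b_i) * (1/m) * sum_{s=1..m} dF/dx_i( b + (s/m)(x-b) )``
    — a Riemann right sum over the straight path from the baseline to the
    input.  For a linear model this is exact at any step count; in general
    the completeness residual shrinks as ``steps`` grows.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x = np.asarray(x, dtype=np.float32)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    b = np.full_like(x, baseline)
    delta = x - b
    total = np.zeros_like(x, dtype=np.float64)
    for s in range(1, steps + 1):
        point = b + (s / steps) * delta
        g = model.input_gradient(point[None, None])
        total += g[0, 0].astype(np.float64)
    attr = delta.astype(np.float64) * total / steps
    return AttributionMap(grid=attr, method="integrated_gradients",
                          baseline=baseline, steps=steps)


def occlusion_map(model: Sequential, x: np.ndarray,
                  window: Tuple[int, ...] | int = 16,
                  stride: Tuple[int, ...] | int | None = None,
                  baseline: float = 0.0) -> AttributionMap:
    """Sliding-window occlusion attribution.

    For each window placement the importance is ``F(x) - F(x_occluded)``;
    every voxel's score is the mean importance over all windows covering it.
    Placements tile the input from index 0 with the given stride, with a
    final placement clamped to the far edge so every voxel is covered.
    """
    x = np.asarray(x, dtype=np.float32)
    ndim = x.ndim
    if isinstance(window, int):
        window = (window,) * ndim
    if stride is None:
        stride = tuple(max(w // 2, 1) for w in window)
    elif isinstance(stride, int):
        stride = (stride,) * ndim
    if any(w > n for w, n in zip(window, x.shape)):
        raise ValueError("occlusion window larger than the input")
    if any(s < 1 for s in stride):
        raise ValueError("stride must be >= 1")

    def starts(n, w, s):
        ss = list(range(0, n - w + 1, s))
        if ss[-1] != n - w:
            ss.append(n - w)
        return ss

    base_out = _logit(model, x)
    importance = np.zeros(x.shape, dtype=np.float64)
    coverage = np.zeros(x.shape, dtype=np.int64)
    axes_starts = [starts(n, w, s) for n, w, s in zip(x.shape, window, stride)]
    for corner in itertools.product(*axes_starts):
        sl = tuple(slice(c, c + w) for c, w in zip(corner, window))
        occluded = x.copy()
        occluded[sl] = baseline
        imp = base_out - _logit(model, occluded)
        importance[sl] += imp
        coverage[sl] += 1
    return AttributionMap(grid=importance / np.maximum(coverage, 1),
                          method="occlusion", baseline=baseline,
                          window=window, stride=stride)


def summarize_slice(attribution: AttributionMap) -> Tuple[int, np.ndarray]:
    """Pick the most informative slice of a 3-D attribution map.

    Returns ``(index, 2-D map)`` of the slice (last grid axis) with maximal
    total absolute attribution; ties resolve to the lowest index.
    """
    grid = attribution.grid
    if grid.ndim != 3:
        raise ValueError("summarize_slice expects a 3-D attribution map")
    totals = np.abs(grid).sum(axis=(0, 1))
    idx = int(np.argmax(totals))  # argmax returns the first (lowest) maximum
    return idx, grid[:, :, idx]
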