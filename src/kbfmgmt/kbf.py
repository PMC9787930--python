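"""Knowledge-Based Filtering: unsupervised multimodal tumor-ROI preselection.

Two radiological facts about glioma on standard sequences drive the filter:
on FLAIR the lesion is the brightest tissue in the brain, and on T1-w its
intensity sits between cerebrospinal fluid (dark) and normal parenchyma.
The filter therefore

1. computes the intensity mode over in-brain voxels of each sequence and
   keeps FLAIR voxels strictly *above* the FLAIR mode and T1-w voxels
   strictly *below* the T1-w mode (values near the mode are overwhelmingly
   normal tissue);
2. of those survivors keeps the top ``tail_fraction`` (default 25 %) by
   intensity on FLAIR and the bottom ``tail_fraction`` on T1-w;
3. intersects the two selections ("cross-intersection"): a voxel must look
   tumor-like in *both* sequences to survive.

The resulting mask multiplies the FLAIR volume voxel-wise, the product is
cropped to a fixed cube centred on the brain (shifted only as far as needed
to keep every selected voxel) and min-max normalised to [0, 1] per patient.
The aim is localisation, not pixel-accurate segmentation: the mask forms a
large cluster over a lesion plus sparse outliers, or only sparse outliers
when no lesion is present.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .volume import BrainMask, EmptyBrainError, ROIMask, Volume

__all__ = [
    "KBFParams",
    "intensity_mode",
    "mode_split",
    "quantile_select",
    "kbf_mask",
    "apply_roi",
    "crop_and_normalize",
    "ROIOverflowError",
]


class ROIOverflowError(ValueError):
    """The preselected ROI does not fit inside the crop window."""


@dataclass
class KBFParams:
    """Tuning knobs of the knowledge-based filter.

    tail_fraction:
        Fraction of the post-mode-split voxels kept at the quantile stage
        (``0 < f <= 0.5``; default 0.25, i.e. the 25 % extreme tail).
    scope:
        ``"per_volume"`` runs the whole procedure once on the 3-D volume;
        ``"per_slice"`` repeats it independently on every 2-D slice.
    mode_bins:
        Histogram bin count used for the mode of continuous-valued data;
        ``None`` (default) bins integer-valued data at unit width.
    crop_side:
        Edge length in voxels of the output cube (default 192).
    """

    tail_fraction: float = 0.25
    scope: str = "per_volume"
    mode_bins: int | None = None
    crop_side: int = 192

    def __post_init__(self) -> None:
        if not (0.0 < self.tail_fraction <= 0.5):
            raise ValueError("tail_fraction must lie in (0, 0.5]")
        if self.scope not in ("per_volume", "per_slice"):
            raise ValueError("scope must be 'per_volume' or 'per_slice'")
        if self.crop_side < 1:
            raise ValueError("crop_side must be >= 1")
        if self.mode_bins is not None and self.mode_bins < 1:
            raise ValueError("mode_bins must be >= 1")


def intensity_mode(values, bins: int | None = None) -> float:
    """Most frequent intensity of a sample; ties break toward the smallest.

    Integer-valued samples (the default for MR pixel data) are counted at
    unit width; continuous data are histogrammed into ``bins`` equal-width
    bins and the center of the fullest bin is returned.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot take the mode of an empty sample")
    if bins is None:
        if not np.array_equal(values, np.rint(values)):
            raise ValueError(
                "non-integer intensities: pass an explicit bin count"
            )
        ints = values.astype(np.int64)
        offset = ints.min()
        counts = np.bincount(ints - offset)
        return float(np.argmax(counts) + offset)  # argmax: first == smallest
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return lo
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def _split_one(flair: np.ndarray, t1: np.ndarray, brain: np.ndarray,
               bins: int | None) -> Tuple[np.ndarray, np.ndarray]:
    supra = np.zeros_like(brain, dtype=bool)
    sub = np.zeros_like(brain, dtype=bool)
    if brain.any():
        m_f = intensity_mode(flair[brain], bins)
        m_t = intensity_mode(t1[brain], bins)
        supra = brain & (flair > m_f)
        sub = brain & (t1 < m_t)
    return supra, sub


def mode_split(flair: Volume, t1: Volume, brain: BrainMask,
               *, bins: int | None = None) -> Tuple[ROIMask, ROIMask]:
    """First threshold: split each sequence at its in-brain intensity mode.

    Returns the FLAIR voxels strictly above the FLAIR mode and the T1-w
    voxels strictly below the T1-w mode (both restricted to the brain).
    Modes are computed over in-brain voxels only, so the zero background
    cannot masquerade as the most common tissue intensity.
    """
    if flair.grid.shape != t1.grid.shape or flair.grid.shape != brain.grid.shape:
        raise ValueError("FLAIR, T1-w and brain mask must share one shape")
    if not brain.grid.any():
        raise EmptyBrainError("empty brain: mask selects no voxels")
    supra, sub = _split_one(np.asarray(flair.grid, float),
                            np.asarray(t1.grid, float), brain.grid, bins)
    return ROIMask(supra), ROIMask(sub)


def quantile_select(mask: ROIMask, values: Volume, fraction: float,
                    direction: str) -> ROIMask:
    """Second threshold: keep the extreme ``fraction`` tail of masked voxels.

    Exactly ``k = ceil(fraction * n)`` of the ``n`` masked voxels survive —
    the ``k`` largest (``direction="highest"``) or smallest
    (``direction="lowest"``) by intensity.  Intensity ties at the cut are
    resolved by lexicographic (flat C-order) voxel index, making the
    selection deterministic.  An empty mask passes through unchanged.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    if direction not in ("highest", "lowest"):
        raise ValueError("direction must be 'highest' or 'lowest'")
    if mask.grid.shape != values.grid.shape:
        raise ValueError("mask and values must share one shape")
    flat_idx = np.flatnonzero(mask.grid.ravel())
    n = flat_idx.size
    if n == 0:
        return ROIMask(np.zeros_like(mask.grid))
    k = math.ceil(fraction * n)
    vals = np.asarray(values.grid, float).ravel()[flat_idx]
    key = -vals if direction == "highest" else vals
    order = np.argsort(key, kind="stable")  # stable: ties keep index order
    keep = flat_idx[order[:k]]
    out = np.zeros(mask.grid.size, dtype=bool)
    out[keep] = True
    return ROIMask(out.reshape(mask.grid.shape))


def kbf_mask(flair: Volume, t1: Volume, brain: BrainMask,
             params: KBFParams | None = None) -> ROIMask:
    """Full knowledge-based filter: mode split, tail quantiles, intersection.

    With ``scope="per_slice"`` the whole procedure (modes, quantiles and the
    intersection) runs independently on each 2-D slice along the last grid
    axis.  An empty intersection is a valid result (no suspicious voxels) and
    raises a warning rather than an error.
    """
    params = params or KBFParams()
    supra, sub = mode_split(flair, t1, brain, bins=params.mode_bins)
    f = params.tail_fraction
    if params.scope == "per_volume":
        top = quantile_select(supra, flair, f, "highest")
        low = quantile_select(sub, t1, f, "lowest")
        roi = top.grid & low.grid
    else:
        roi = np.zeros_like(brain.grid)
        fg, tg, bg = np.asarray(flair.grid, float), np.asarray(t1.grid, float), brain.grid
        for s in range(brain.grid.shape[2]):
            b2 = bg[:, :, s]
            if not b2.any():
                continue
            supra2, sub2 = _split_one(fg[:, :, s], tg[:, :, s], b2, params.mode_bins)
            top2 = _tail_2d(supra2, fg[:, :, s], f, highest=True)
            low2 = _tail_2d(sub2, tg[:, :, s], f, highest=False)
            roi[:, :, s] = top2 & low2
    if not roi.any():
        warnings.warn("KBF cross-intersection is empty: no suspicious voxels",
                      stacklevel=2)
    return ROIMask(roi)


def _tail_2d(mask2d: np.ndarray, vals2d: np.ndarray, fraction: float,
             highest: bool) -> np.ndarray:
    flat_idx = np.flatnonzero(mask2d.ravel())
    if flat_idx.size == 0:
        return np.zeros_like(mask2d)
    k = math.ceil(fraction * flat_idx.size)
    v = vals2d.ravel()[flat_idx]
    order = np.argsort(-v if highest else v, kind="stable")
    out = np.zeros(mask2d.size, dtype=bool)
    out[flat_idx[order[:k]]] = True
    return out.reshape(mask2d.shape)


def apply_roi(flair: Volume, roi: ROIMask) -> Volume:
    """Point-wise multiplication of the FLAIR volume with the ROI mask."""
    if roi.grid.shape != flair.grid.shape:
        raise ValueError("ROI mask shape does not match volume")
    return flair.with_grid(np.asarray(flair.grid, float) * roi.grid)


def crop_and_normalize(masked_flair: Volume, brain: BrainMask,
                       roi: ROIMask, params: KBFParams | None = None) -> Volume:
    """Crop to a fixed cube around the brain and min-max scale to [0, 1].

    The cube (side ``params.crop_side``) is centred on the brain bounding-box
    center, then shifted the minimal amount per axis so every ROI voxel lies
    inside; regions outside the original volume are zero-padded.  Intensities
    are scaled so the cropped window spans exactly [0, 1]; a constant window
    maps to all zeros.
    """
    params = params or KBFParams()
    side = params.crop_side
    shape = masked_flair.grid.shape
    if brain.grid.shape != shape or roi.grid.shape != shape:
        raise ValueError("inputs must share one shape")
    if not brain.grid.any():
        raise EmptyBrainError("empty brain: mask selects no voxels")

    starts = []
    brain_idx = np.nonzero(brain.grid)
    roi_idx = np.nonzero(roi.grid) if roi.grid.any() else None
    for ax in range(3):
        b_lo, b_hi = int(brain_idx[ax].min()), int(brain_idx[ax].max())
        start = (b_lo + b_hi + 1 - side) // 2  # window centred on brain box
        if roi_idx is not None:
            r_lo, r_hi = int(roi_idx[ax].min()), int(roi_idx[ax].max())
            if r_hi - r_lo + 1 > side:
                raise ROIOverflowError(
                    f"ROI extent {r_hi - r_lo + 1} exceeds crop side {side} "
                    f"on axis {ax}"
                )
            # minimal shift keeping the whole ROI inside the window
            start = min(max(start, r_hi - side + 1), r_lo)
        starts.append(start)

    out = np.zeros((side, side, side), dtype=float)
    src = []
    dst = []
    for ax, start in enumerate(starts):
        lo = max(start, 0)
        hi = min(start + side, shape[ax])
        src.append(slice(lo, hi))
        dst.append(slice(lo - start, hi - start))
    out[tuple(dst)] = np.asarray(masked_flair.grid, float)[tuple(src)]

    lo, hi = float(out.min()), float(out.max())
    if hi > lo:
        out = (out - lo) / (hi - lo)
    else:
        out = np.zeros_like(out)
    return Volume(grid=out, spacing=masked_flair.spacing,
                  orientation_tag=masked_flair.orientation_tag,
                  modality=masked_flair.modality,
                  patient_id=masked_flair.patient_id)
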