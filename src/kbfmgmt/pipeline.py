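"""End-to-end glue: preparation -> knowledge-based filtering -> model input.

These helpers chain the stage modules for a single subject and for whole
cohorts, producing the fixed-size, [0, 1]-normalised, ROI-masked FLAIR cube
the classifier consumes.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from . import kbf as kbf_mod
from . import prep
from .kbf import KBFParams
from .synthdata import Phantom
from .train_eval import ArrayDataset
from .volume import BrainMask, Volume

__all__ = ["prepare_input", "phantoms_to_dataset", "informative_slices"]

logger = logging.getLogger("kbfmgmt.pipeline")


def _resample_mask(mask: BrainMask, spacing) -> BrainMask:
    vol = Volume(grid=mask.grid.astype(float), spacing=spacing)
    iso = prep.resample_isotropic(vol, interpolation="nearest")
    return BrainMask(grid=iso.grid > 0.5, source=mask.source)


def prepare_input(flair: Volume, t1: Volume, brain: BrainMask,
                  params: Optional[KBFParams] = None,
                  register: bool = False) -> np.ndarray:
    """Run one subject through the full preprocessing chain.

    Resamples to 1 mm isotropic, reorients to the sagittal-standard frame,
    optionally rigidly aligns T1-w onto FLAIR, skull-strips, applies the
    knowledge-based filter and returns the cropped normalised cube
    (``params.crop_side`` per edge).
    """
    params = params or KBFParams()
    flair = prep.reorient_to_sagittal(flair)
    t1 = prep.reorient_to_sagittal(t1)
    if flair.spacing != (1.0, 1.0, 1.0):
        brain = _resample_mask(brain, flair.spacing)
        # interpolated intensities are re-quantised to the integer scale the
        # acquisition used, keeping the mode histogram well defined
        flair = prep.resample_isotropic(flair)
        flair = flair.with_grid(np.rint(flair.grid))
    if t1.spacing != (1.0, 1.0, 1.0):
        t1 = prep.resample_isotropic(t1)
        t1 = t1.with_grid(np.rint(t1.grid))
    if register:
        transform = prep.register_rigid(t1, flair)
        t1 = prep.apply_rigid(t1, transform, flair)
    flair = prep.apply_brain_mask(flair, brain)
    t1 = prep.apply_brain_mask(t1, brain)
    logger.debug("prepared %s: shape=%s brain voxels=%d",
                 flair.patient_id, flair.shape, brain.n_voxels)
    roi = kbf_mod.kbf_mask(flair, t1, brain, params)
    logger.debug("KBF %s: %d ROI voxels", flair.patient_id, roi.n_voxels)
    masked = kbf_mod.apply_roi(flair, roi)
    cropped = kbf_mod.crop_and_normalize(masked, brain, roi, params)
    return cropped.grid


def informative_slices(cube: np.ndarray, max_slices: int | None = None
                       ) -> np.ndarray:
    """Stack of 2D slices (along the last axis) that contain ROI signal.

    Used by the 2D classifier variant; slices are ranked by total intensity
    and optionally capped at ``max_slices``.
    """
    sums = cube.sum(axis=(0, 1))
    idx = np.flatnonzero(sums > 0)
    if idx.size == 0:
        idx = np.array([cube.shape[2] // 2])
    if max_slices is not None and idx.size > max_slices:
        order = np.argsort(-sums[idx], kind="stable")
        idx = np.sort(idx[order[:max_slices]])
    return np.stack([cube[:, :, i] for i in idx])


def phantoms_to_dataset(phantoms: Sequence[Phantom], name: str = "synthetic",
                        params: Optional[KBFParams] = None, dims: int = 3,
                        max_slices: int | None = 16) -> ArrayDataset:
    """Run a cohort through the pipeline into a training-ready dataset.

    Phantom KBF parameters default to integer-mode binning; the KBF mode
    histogram needs no bin count because phantom intensities are integral.
    """
    params = params or KBFParams()
    samples = []
    for ph in phantoms:
        cube = prepare_input(ph.flair, ph.t1, ph.brain_mask, params)
        if dims == 2:
            x = informative_slices(cube, max_slices)
        else:
            x = cube
        samples.append((ph.flair.patient_id, x.astype(np.float32), ph.label))
    return ArrayDataset(name=name, samples=samples)
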