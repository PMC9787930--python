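"""Seeded synthetic brain phantoms: paired FLAIR/T1-w volumes with ground truth.

A phantom is an ellipsoidal "brain" containing ventricle-like CSF cavities
and zero or more roughly spherical tumor blobs, voxelised on a regular grid
and corrupted with Gaussian noise.  Class mean intensities encode the two
radiological facts the ROI preselection relies on:

* T1-w:  mean(CSF) < mean(tumor) < mean(parenchyma)  (tumor darker than
  normal tissue but brighter than fluid);
* FLAIR: mean(tumor) > mean(any other tissue)  (lesion hyperintense).

The binary methylation label is carried by tumor *texture* on FLAIR, not by
mean intensity: in positive subjects the tumor interior is modulated by a
spatially correlated multiplicative heterogeneity field (zero mean and unit
variance within the tumor, correlation length a fraction of the tumor
radius, relative amplitude ``label_effect``), in negative subjects it is
smooth.  The ROI preselection is therefore label-agnostic (both classes
yield the same kind of mask) and a classifier must exploit within-ROI
structure — mirroring the premise that methylation status is not trivially
visible in overall lesion brightness.

Grids are emitted integer-rounded (the common MR pixel dialect), so phantoms
round-trip bit-exactly through the DICOM writer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import dicom_io, prep
from .volume import SAGITTAL_CODE, BrainMask, Volume

__all__ = ["PhantomParams", "Phantom", "make_phantom", "make_cohort"]

_DEFAULT_MEANS = {
    "FLAIR": {"csf": 60.0, "parenchyma": 120.0, "tumor": 200.0},
    "T1w": {"csf": 60.0, "tumor": 110.0, "parenchyma": 160.0},
}


@dataclass
class PhantomParams:
    """Geometry, intensity and label-signal parameters of a phantom.

    Lengths are fractions of ``grid_side`` so presets scale cleanly;
    intensities are in arbitrary MR units.  ``label_effect`` is the relative
    amplitude of the methylation-conditional tumor texture on FLAIR.
    """

    grid_side: int = 96
    spacing: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_axes: Tuple[float, float, float] = (0.42, 0.36, 0.40)
    csf_fraction: float = 0.04
    tumor_count: int = 1
    tumor_radius_range: Tuple[float, float] = (0.08, 0.12)
    means: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in _DEFAULT_MEANS.items()}
    )
    noise_sd: float = 8.0
    label_effect: float = 0.25
    texture_scale: float = 0.04  # heterogeneity correlation length / grid_side

    def __post_init__(self) -> None:
        if self.grid_side < 16:
            raise ValueError("grid_side must be >= 16")
        if self.tumor_count < 0:
            raise ValueError("tumor_count must be >= 0")
        if self.noise_sd < 0 or self.label_effect < 0:
            raise ValueError("noise_sd and label_effect must be >= 0")
        t1, fl = self.means["T1w"], self.means["FLAIR"]
        if not (t1["csf"] < t1["tumor"] < t1["parenchyma"]):
            raise ValueError(
                "T1-w means must satisfy CSF < tumor < parenchyma"
            )
        if not fl["tumor"] > max(fl["csf"], fl["parenchyma"]):
            raise ValueError("FLAIR tumor mean must exceed every other tissue")

    @classmethod
    def small(cls, **overrides) -> "PhantomParams":
        """Fast preset (48-voxel grid at 1 mm) for unit tests and CPU runs."""
        kw = {"grid_side": 48, "spacing": (1.0, 1.0, 1.0), **overrides}
        return cls(**kw)

    @classmethod
    def full_scale(cls, **overrides) -> "PhantomParams":
        """Acquisition-scale preset: 192-voxel grid at 1 mm isotropic."""
        kw = {"grid_side": 192, "spacing": (1.0, 1.0, 1.0), **overrides}
        return cls(**kw)


@dataclass
class Phantom:
    """A synthetic subject: aligned FLAIR/T1-w pair plus ground truth."""

    flair: Volume
    t1: Volume
    brain_mask: BrainMask
    tumor_mask: np.ndarray
    label: int
    meta: Dict

    def __post_init__(self) -> None:
        assert self.tumor_mask.shape == self.flair.grid.shape
        assert not (self.tumor_mask & ~self.brain_mask.grid).any(), \
            "tumor mask must be inside the brain mask"


def _ellipsoid(coords, center, semi_axes) -> np.ndarray:
    d = sum(((c - o) / a) ** 2 for c, o, a in zip(coords, center, semi_axes))
    return d <= 1.0


def make_phantom(params: PhantomParams, seed: int,
                 label: Optional[int] = None,
                 patient_id: str = "anon") -> Phantom:
    """Generate one phantom, fully reproducible per ``(params, seed, label)``.

    ``label`` defaults to a fair coin flip from the same seeded stream.
    Empirical class-mean orderings are asserted on the emitted volumes, not
    just assumed from the configured means.
    """
    rng = np.random.default_rng(seed)
    n = params.grid_side
    coords = np.meshgrid(*[np.arange(n, dtype=float)] * 3, indexing="ij")
    center = np.full(3, (n - 1) / 2.0)

    brain = _ellipsoid(coords, center, [a * n for a in params.brain_axes])

    # ventricle-like CSF cavities, mirrored about the mid-plane
    scale = (params.csf_fraction / 0.04) ** (1.0 / 3.0)
    vent_axes = [0.14 * n * scale, 0.055 * n * scale, 0.10 * n * scale]
    offset = 0.09 * n
    csf = np.zeros_like(brain)
    for sign in (-1.0, 1.0):
        c = center + np.array([0.0, sign * offset, 0.0])
        csf |= _ellipsoid(coords, c, vent_axes)
    csf &= brain

    # tumor blobs: random centers well inside the brain, spheroidal
    tumor = np.zeros_like(brain)
    lo, hi = params.tumor_radius_range
    for _ in range(params.tumor_count):
        for _attempt in range(100):
            u = rng.uniform(-0.5, 0.5, size=3)
            c = center + u * np.array([a * n for a in params.brain_axes])
            r = rng.uniform(lo, hi) * n
            ax = r * rng.uniform(0.85, 1.15, size=3)
            blob = _ellipsoid(coords, c, ax)
            if (blob & ~brain).sum() == 0 and (blob & csf).sum() == 0:
                tumor |= blob
                break
    parenchyma = brain & ~csf & ~tumor

    if label is None:
        label = int(rng.random() < 0.5)
    label = int(label)

    vols = {}
    for modality in ("FLAIR", "T1w"):
        means = params.means[modality]
        grid = np.zeros((n, n, n), dtype=float)
        grid[csf] = means["csf"]
        grid[parenchyma] = means["parenchyma"]
        grid[tumor] = means["tumor"]
        if (modality == "FLAIR" and label == 1 and tumor.any()
                and params.label_effect > 0):
            field = _heterogeneity_field(tumor, params.texture_scale * n, rng)
            grid[tumor] *= 1.0 + params.label_effect * field
        grid += rng.normal(0.0, params.noise_sd, size=grid.shape)
        grid[~brain] = 0.0
        grid = np.clip(np.rint(grid), 0, 65535)
        vols[modality] = Volume(grid=grid, spacing=params.spacing,
                                orientation_tag=SAGITTAL_CODE,
                                modality=modality, patient_id=patient_id)

    _assert_orderings(vols, csf, parenchyma, tumor)
    meta = {
        "patient_id": patient_id,
        "seed": int(seed),
        "grid_side": n,
        "spacing": list(params.spacing),
        "pixel_spacing": [params.spacing[0], params.spacing[1]],
        "spacing_between_slices": params.spacing[2],
        "image_orientation": list(dicom_io.SAGITTAL_IOP),
    }
    return Phantom(flair=vols["FLAIR"], t1=vols["T1w"],
                   brain_mask=BrainMask(grid=brain, source="external"),
                   tumor_mask=tumor, label=label, meta=meta)


def _heterogeneity_field(tumor: np.ndarray, sigma: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Smooth random field over the tumor voxels: zero mean, unit SD,
    clipped at +/-1.5 so dark pockets stay well above CSF intensity."""
    from scipy.ndimage import gaussian_filter

    raw = gaussian_filter(rng.normal(size=tumor.shape), sigma=sigma)
    vals = raw[tumor]
    sd = vals.std()
    if sd < 1e-12:
        return np.zeros(int(tumor.sum()))
    vals = (vals - vals.mean()) / sd
    return np.clip(vals, -1.5, 1.5)


def _assert_orderings(vols, csf, parenchyma, tumor) -> None:
    if not tumor.any():
        return
    f, t = vols["FLAIR"].grid, vols["T1w"].grid
    if not (f[tumor].mean() > f[parenchyma].mean() > f[csf].mean()):
        raise AssertionError("FLAIR empirical class-mean ordering violated")
    if not (t[csf].mean() < t[tumor].mean() < t[parenchyma].mean()):
        raise AssertionError("T1-w empirical class-mean ordering violated")


def make_cohort(n: int, prevalence: float, params: PhantomParams, seed: int,
                out_dir=None, prefix: str = "P"
                ) -> Tuple[List[Phantom], pd.DataFrame]:
    """Generate ``n`` independent phantoms with ``round(prevalence * n)``
    positive labels, optionally materialised on disk.

    The on-disk layout mimics a real cohort: one DICOM series directory per
    subject and modality, NIfTI ground-truth masks, a ``labels.csv``
    (``patient_id,label``) and a JSON manifest of the generation parameters.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_pos = int(round(prevalence * n))
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    seeds = rng.integers(0, 2**31 - 1, size=n)

    phantoms: List[Phantom] = []
    rows = []
    for i in range(n):
        pid = f"{prefix}{i:03d}"
        ph = make_phantom(params, int(seeds[i]), label=int(labels[i]),
                          patient_id=pid)
        phantoms.append(ph)
        rows.append({"patient_id": pid, "label": int(labels[i])})
    labels_df = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for ph in phantoms:
            pdir = out_dir / ph.meta["patient_id"]
            dicom_io.write_series(ph.flair, pdir / "FLAIR")
            dicom_io.write_series(ph.t1, pdir / "T1w")
            prep.save_nifti(ph.brain_mask, pdir / "brain_mask.nii.gz")
            _save_binary(ph.tumor_mask, pdir / "tumor_mask.nii.gz")
        labels_df.to_csv(out_dir / "labels.csv", index=False)
        manifest = {"n": n, "prevalence": prevalence, "seed": int(seed),
                    "params": asdict(params)}
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return phantoms, labels_df


def _save_binary(mask: np.ndarray, path) -> None:
    import nibabel as nib
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.eye(4)), str(path))
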