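"""Core in-memory containers shared by every pipeline stage.

A :class:`Volume` is a 3-D intensity grid indexed ``(row, column, slice)``
(0-based) together with its physical voxel spacing in millimetres and an
anatomical orientation code in DICOM LPS patient space.  Binary masks
(:class:`BrainMask`, :class:`ROIMask`) always share the shape of the volume
they refer to.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

__all__ = [
    "Volume",
    "BrainMask",
    "ROIMask",
    "MODALITIES",
    "SAGITTAL_CODE",
    "orientation_code",
    "EmptyBrainError",
]

#: Recognised MRI series names.
MODALITIES = ("FLAIR", "T1w", "T1wCE", "T2w")

#: Orientation code of the standard sagittal frame this pipeline normalises
#: to: grid axis 0 (rows) runs Inferior, axis 1 (columns) runs Posterior,
#: axis 2 (slices) runs toward the patient Right.  It corresponds to DICOM
#: ImageOrientationPatient ``(0, 1, 0, 0, 0, -1)``.
SAGITTAL_CODE = "IPR"

_AXIS_LETTERS = {
    (1, 0, 0): "L",
    (-1, 0, 0): "R",
    (0, 1, 0): "P",
    (0, -1, 0): "A",
    (0, 0, 1): "S",
    (0, 0, -1): "I",
}


class EmptyBrainError(ValueError):
    """Raised when a brain mask is empty where a nonempty one is required."""


def orientation_code(image_orientation) -> str:
    """Derive the 3-letter grid-axis orientation code from the 6 DICOM
    direction cosines ``(row_x, row_y, row_z, col_x, col_y, col_z)``.

    The code letters give, per grid axis ``(row, column, slice)``, the LPS
    patient-space direction the axis runs along.  Cosines are rounded to the
    nearest of {-1, 0, 1}; returns ``"oblique"`` when the rounded vectors are
    not an orthogonal axis permutation.
    """
    iop = np.asarray(image_orientation, dtype=float)
    if iop.shape != (6,):
        raise ValueError("image orientation must have 6 direction cosines")
    row, col = iop[:3], iop[3:]
    for v in (row, col):
        if abs(np.linalg.norm(v) - 1.0) > 1e-4:
            raise ValueError("direction cosines must have unit norm")
    r = np.rint(row).astype(int)
    c = np.rint(col).astype(int)
    normal = np.cross(row, col)
    n = np.rint(normal).astype(int)
    vecs = [tuple(c), tuple(r), tuple(n)]  # grid axes: rows move along col cosines
    if any(v not in _AXIS_LETTERS for v in vecs):
        return "oblique"
    letters = [_AXIS_LETTERS[v] for v in vecs]
    if len({ax.translate(str.maketrans("RAI", "LPS")) for ax in letters}) != 3:
        return "oblique"
    return "".join(letters)


@dataclass
class Volume:
    """A 3-D acquisition: intensity grid + voxel spacing + orientation.

    Parameters
    ----------
    grid:
        3-D float array indexed ``(row, column, slice)``.
    spacing:
        ``(sx, sy, sz)`` voxel edge lengths in mm along the grid axes.
    orientation_tag:
        3-letter LPS axis code (see :func:`orientation_code`) or ``"oblique"``.
    modality:
        One of :data:`MODALITIES`.
    patient_id:
        Opaque subject identifier.
    """

    grid: np.ndarray
    spacing: Tuple[float, float, float]
    orientation_tag: str = SAGITTAL_CODE
    modality: str = "FLAIR"
    patient_id: str = "anon"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError("grid must be 3-D with each dimension >= 1")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.grid.shape

    def with_grid(self, grid, spacing=None, orientation_tag=None) -> "Volume":
        """Copy of this volume carrying new voxel data (metadata preserved)."""
        return replace(
            self,
            grid=grid,
            spacing=self.spacing if spacing is None else spacing,
            orientation_tag=self.orientation_tag
            if orientation_tag is None
            else orientation_tag,
        )


def _check_binary(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise ValueError("mask grid must be 3-D")
    if grid.dtype != bool:
        vals = np.unique(grid)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be binary")
        grid = grid.astype(bool)
    return grid


@dataclass
class BrainMask:
    """Binary mask of intracranial voxels; ``source`` records provenance."""

    grid: np.ndarray
    source: str = "external"  # {external, fallback}

    def __post_init__(self) -> None:
        self.grid = _check_binary(self.grid)
        if self.source not in ("external", "fallback"):
            raise ValueError("source must be 'external' or 'fallback'")
        if self.source == "external" and not self.grid.any():
            raise EmptyBrainError("external brain mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


@dataclass
class ROIMask:
    """Binary mask of preselected suspicious voxels."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = _check_binary(self.grid)

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    def __and__(self, other: "ROIMask") -> "ROIMask":
        return ROIMask(self.grid & other.grid)
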