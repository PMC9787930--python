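"""DICOM series reconstruction and emission.

Real brain-MRI cohorts ship one DICOM part-10 file per slice; the four tags
that matter for geometry are Slice Location, Pixel Spacing, Spacing Between
Slices and Image Orientation (Patient).  :func:`assemble_volume` stacks the
slices of one series, ordered by Slice Location, into a :class:`~kbfmgmt.volume.Volume`
whose voxel spacing is ``(row_spacing, column_spacing, spacing_between_slices)``
in mm.  :func:`write_series` is the inverse used to exercise the ingestion
path on synthetic data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage, generate_uid

from .volume import MODALITIES, Volume, orientation_code

__all__ = [
    "SliceRecord",
    "assemble_volume",
    "write_series",
    "read_series",
    "AmbiguousOrderingError",
    "InconsistentSeriesError",
]


class AmbiguousOrderingError(ValueError):
    """Two slices of a series share the same Slice Location."""


class InconsistentSeriesError(ValueError):
    """Slices of a series disagree on shape, spacing, orientation or subject."""


#: Standard DICOM direction cosines of the sagittal frame (rows run
#: Posterior, columns run Inferior) — the orientation synthetic series use.
SAGITTAL_IOP: Tuple[float, ...] = (0.0, 1.0, 0.0, 0.0, 0.0, -1.0)


@dataclass
class SliceRecord:
    """One 2-D slice plus the acquisition metadata needed to stack it."""

    pixel_grid: np.ndarray
    slice_location: float
    pixel_spacing: Tuple[float, float]
    spacing_between_slices: float
    image_orientation: Tuple[float, ...]
    series_modality: str
    patient_id: str = "anon"

    def __post_init__(self) -> None:
        self.pixel_grid = np.asarray(self.pixel_grid)
        if self.pixel_grid.ndim != 2:
            raise ValueError("pixel_grid must be 2-D")
        if not np.all(np.isfinite(self.pixel_grid)):
            raise ValueError("pixel_grid contains non-finite values")
        self.pixel_spacing = tuple(float(s) for s in self.pixel_spacing)
        self.spacing_between_slices = float(self.spacing_between_slices)
        if any(s <= 0 for s in self.pixel_spacing) or self.spacing_between_slices <= 0:
            raise ValueError("spacings must be positive")
        self.image_orientation = tuple(float(c) for c in self.image_orientation)
        orientation_code(self.image_orientation)  # validates norm / length
        if self.series_modality not in MODALITIES:
            raise ValueError(f"unknown series modality {self.series_modality!r}")


def _series_key(s: SliceRecord):
    return (
        s.patient_id,
        s.series_modality,
        s.pixel_grid.shape,
        s.pixel_spacing,
        round(s.spacing_between_slices, 6),
        tuple(round(c, 6) for c in s.image_orientation),
    )


def assemble_volume(slices: Sequence[SliceRecord]) -> Volume:
    """Stack a DICOM series into a 3-D volume, ordered by Slice Location.

    Slices are sorted in ascending ``slice_location``; the result's spacing is
    ``(row_spacing, column_spacing, spacing_between_slices)``.  The stack
    order is therefore invariant to the order the files were read in.

    Raises
    ------
    AmbiguousOrderingError
        If two slices share a Slice Location.
    InconsistentSeriesError
        If the slices disagree on subject, modality, shape, spacing or
        orientation.
    """
    if len(slices) == 0:
        raise ValueError("cannot assemble an empty series")
    keys = {_series_key(s) for s in slices}
    if len(keys) != 1:
        raise InconsistentSeriesError(
            "inconsistent series: slices differ in shape, spacing, "
            "orientation, modality or subject"
        )
    locs = [s.slice_location for s in slices]
    if len(set(locs)) != len(locs):
        raise AmbiguousOrderingError(
            "ambiguous ordering: duplicate Slice Location values"
        )
    ordered = sorted(slices, key=lambda s: s.slice_location)
    grid = np.stack([s.pixel_grid for s in ordered], axis=-1).astype(float)
    first = ordered[0]
    return Volume(
        grid=grid,
        spacing=(first.pixel_spacing[0], first.pixel_spacing[1], first.spacing_between_slices),
        orientation_tag=orientation_code(first.image_orientation),
        modality=first.series_modality,
        patient_id=first.patient_id,
    )


def _iop_for_code(tag: str) -> Tuple[float, ...]:
    # invert orientation_code for the axis-aligned frames we emit
    letter_vec = {
        "L": (1, 0, 0), "R": (-1, 0, 0),
        "P": (0, 1, 0), "A": (0, -1, 0),
        "S": (0, 0, 1), "I": (0, 0, -1),
    }
    if tag == "oblique" or len(tag) != 3:
        raise ValueError("cannot emit DICOM for an oblique orientation")
    col = letter_vec[tag[0]]  # rows move along the column cosines
    row = letter_vec[tag[1]]
    return tuple(float(x) for x in row + col)


def write_series(vol: Volume, out_dir) -> List[Path]:
    """Emit one uint16 DICOM part-10 file per slice of ``vol``.

    Grid values must be integer-valued in ``[0, 65535]`` (the common MR pixel
    dialect) so that ``assemble_volume(read_series(...))`` reproduces the grid
    bit-exactly.  Slice Locations form the arithmetic sequence
    ``0, sz, 2*sz, ...``.
    """
    grid = np.asarray(vol.grid)
    if not np.all(np.isfinite(grid)):
        raise ValueError("volume contains non-finite values")
    if not np.array_equal(grid, np.rint(grid)) or grid.min() < 0 or grid.max() > 65535:
        raise ValueError("write_series requires integer-valued grids in [0, 65535]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    iop = _iop_for_code(vol.orientation_tag)
    series_uid = generate_uid()
    paths: List[Path] = []
    for k in range(grid.shape[2]):
        ds = Dataset()
        ds.PatientID = vol.patient_id
        ds.Modality = "MR"
        ds.SeriesDescription = vol.modality
        ds.SeriesInstanceUID = series_uid
        ds.SOPClassUID = MRImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = grid.shape[0], grid.shape[1]
        ds.PixelSpacing = [vol.spacing[0], vol.spacing[1]]
        ds.SpacingBetweenSlices = vol.spacing[2]
        ds.SliceLocation = k * vol.spacing[2]
        ds.ImageOrientationPatient = list(iop)
        ds.ImagePositionPatient = [0.0, 0.0, float(k * vol.spacing[2])]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.ascontiguousarray(grid[:, :, k].astype(np.uint16)).tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = MRImageStorage
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        path = out_dir / f"{vol.modality}-{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def read_series(series_dir, modality: str | None = None) -> List[SliceRecord]:
    """Read every DICOM file under ``series_dir`` into slice records.

    ``modality`` optionally restricts to one series description when a
    directory mixes several series.
    """
    series_dir = Path(series_dir)
    records: List[SliceRecord] = []
    for name in sorted(os.listdir(series_dir)):
        path = series_dir / name
        if path.is_dir() or not name.lower().endswith(".dcm"):
            continue
        ds = pydicom.dcmread(path)
        desc = str(getattr(ds, "SeriesDescription", ""))
        if modality is not None and desc != modality:
            continue
        if "SliceLocation" not in ds:
            raise ValueError(f"{name}: Slice Location tag absent; ordering undefined")
        records.append(
            SliceRecord(
                pixel_grid=ds.pixel_array.astype(float),
                slice_location=float(ds.SliceLocation),
                pixel_spacing=(float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1])),
                spacing_between_slices=float(ds.SpacingBetweenSlices),
                image_orientation=tuple(float(c) for c in ds.ImageOrientationPatient),
                series_modality=desc if desc in MODALITIES else "FLAIR",
                patient_id=str(ds.PatientID),
            )
        )
    if not records:
        raise FileNotFoundError(f"no DICOM slices found in {series_dir}")
    return records
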