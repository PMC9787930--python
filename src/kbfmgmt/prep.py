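"""Volume preparation: isotropic resampling, reorientation to a standard
sagittal frame, inter-modality rigid registration and skull stripping.

The pipeline expects volumes that are already co-registered to a common
template; this module only handles per-subject geometry: bringing every
acquisition to 1 mm isotropic spacing, rotating axis-aligned volumes into the
sagittal-standard frame, aligning modalities to each other with a rigid
(6 degrees of freedom) transform, and zeroing everything outside a brain
mask.  Brain masks are preferably supplied externally (e.g. produced by a
dedicated skull-stripping network); :func:`fallback_brain_mask` provides a
simple intensity-based alternative for data where none is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import SimpleITK as sitk
import nibabel as nib
from scipy import ndimage
from scipy.spatial.transform import Rotation
from skimage.filters import threshold_otsu

from .volume import SAGITTAL_CODE, BrainMask, EmptyBrainError, Volume

__all__ = [
    "RigidTransform",
    "resample_isotropic",
    "reorient_to_sagittal",
    "register_rigid",
    "apply_rigid",
    "apply_brain_mask",
    "fallback_brain_mask",
    "save_nifti",
    "load_nifti",
    "load_mask_nifti",
]


# --------------------------------------------------------------------------
# rigid transforms
# --------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """A 6-DOF transform: Euler angles (degrees, x-y-z order as used by the
    underlying Euler3D parameterisation) plus a translation in mm.

    Convention: the transform maps *fixed*-space physical points to
    *moving*-space points (the resampling convention), rotating about
    ``center`` (mm).  A moving image whose content is the fixed image shifted
    by ``+d`` mm is therefore recovered with ``translation == +d``.
    """

    rotation: Tuple[float, float, float]
    translation: Tuple[float, float, float]
    center: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.rotation = tuple(float(a) for a in self.rotation)
        self.translation = tuple(float(t) for t in self.translation)
        self.center = tuple(float(c) for c in self.center)
        if any(not (-180.0 < a <= 180.0) for a in self.rotation):
            raise ValueError("Euler angles must lie in (-180, 180] degrees")

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix acting on physical (mm) coordinates."""
        rx, ry, rz = np.deg2rad(self.rotation)
        R = (
            Rotation.from_euler("z", rz)
            * Rotation.from_euler("y", ry)
            * Rotation.from_euler("x", rx)
        ).as_matrix()
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = c - R @ c + t
        return M

    def inverse(self) -> "RigidTransform":
        Minv = np.linalg.inv(self.as_matrix())
        R = Rotation.from_matrix(Minv[:3, :3])
        rz, ry, rx = R.as_euler("ZYX", degrees=True)
        c = np.asarray(self.center)
        t = Minv[:3, 3] - c + Minv[:3, :3] @ c
        return RigidTransform((rx, ry, rz), tuple(t), self.center)


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------

def _resample_axis(arr: np.ndarray, axis: int, n_out: int, spacing: float,
                   order: int) -> np.ndarray:
    """1-D (separable) resampling of one axis to 1 mm steps."""
    n = arr.shape[axis]
    pos = np.arange(n_out) / spacing  # input-index coordinate of each output sample
    if order == 0:
        idx = np.clip(np.rint(pos).astype(int), 0, n - 1)
        return np.take(arr, idx, axis=axis)
    i0 = np.clip(np.floor(pos).astype(int), 0, n - 1)
    i1 = np.clip(i0 + 1, 0, n - 1)
    w = np.clip(pos - i0, 0.0, 1.0)
    shape = [1] * arr.ndim
    shape[axis] = n_out
    w = w.reshape(shape)
    return np.take(arr, i0, axis=axis) * (1.0 - w) + np.take(arr, i1, axis=axis) * w


def resample_isotropic(vol: Volume, *, interpolation: str = "linear") -> Volume:
    """Resample a volume to 1x1x1 mm voxels.

    The voxel-center extent convention is used: along an axis of ``n`` voxels
    at spacing ``s`` mm the output has ``round((n - 1) * s) + 1`` samples, so
    the first and last voxel centers coincide with the input's.  Trilinear
    interpolation for intensities (``interpolation="nearest"`` for masks);
    interpolated values never leave the input's ``[min, max]`` range.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError("interpolation must be 'linear' or 'nearest'")
    order = 1 if interpolation == "linear" else 0
    grid = np.asarray(vol.grid, dtype=float)
    for axis, s in enumerate(vol.spacing):
        n_out = int(round((grid.shape[axis] - 1) * s)) + 1
        if n_out != grid.shape[axis] or s != 1.0:
            grid = _resample_axis(grid, axis, n_out, s, order)
    return vol.with_grid(grid, spacing=(1.0, 1.0, 1.0))


# --------------------------------------------------------------------------
# reorientation
# --------------------------------------------------------------------------

_OPPOSITE = {"L": "R", "R": "L", "A": "P", "P": "A", "S": "I", "I": "S"}


def reorient_to_sagittal(vol: Volume) -> Volume:
    """Permute/flip grid axes so the volume sits in the sagittal-standard
    frame (axis code ``IPR``).  Lossless for axis-aligned volumes; identity
    when the volume is already sagittal-standard.
    """
    tag = vol.orientation_tag
    if tag == SAGITTAL_CODE:
        return vol
    if len(tag) != 3 or any(ch not in _OPPOSITE for ch in tag):
        raise ValueError(
            f"cannot reorient orientation {tag!r}: direction cosines are not "
            "axis-aligned"
        )
    perm = []
    flips = []
    for target in SAGITTAL_CODE:
        matches = [i for i, ch in enumerate(tag) if ch in (target, _OPPOSITE[target])]
        if len(matches) != 1:
            raise ValueError(f"degenerate orientation code {tag!r}")
        i = matches[0]
        perm.append(i)
        flips.append(tag[i] == _OPPOSITE[target])
    grid = np.transpose(vol.grid, perm)
    for axis, flip in enumerate(flips):
        if flip:
            grid = np.flip(grid, axis=axis)
    spacing = tuple(vol.spacing[i] for i in perm)
    return vol.with_grid(np.ascontiguousarray(grid), spacing=spacing,
                         orientation_tag=SAGITTAL_CODE)


# --------------------------------------------------------------------------
# rigid registration (inter-modality)
# --------------------------------------------------------------------------

def _to_sitk(vol: Volume) -> sitk.Image:
    # sitk.GetImageFromArray maps array index [k, j, i] -> image index (i, j, k);
    # transpose so image axis x/y/z == grid axis 0/1/2.
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(vol.grid, (2, 1, 0))).astype(np.float32)
    )
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    return img


def register_rigid(moving: Volume, fixed: Volume, *, bins: int = 32,
                   levels: int = 3) -> RigidTransform:
    """Estimate the 6-DOF transform aligning ``moving`` onto ``fixed``.

    Mattes mutual information (suitable across MRI contrasts) is maximised by
    a multi-resolution gradient-descent search (coarse-to-fine shrink factors
    ``2**(levels-1) ... 1``).  Both volumes should already be isotropic and in
    the same orientation frame.
    """
    f_img, m_img = _to_sitk(fixed), _to_sitk(moving)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=bins)
    reg.SetMetricSamplingStrategy(reg.NONE)  # all voxels: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=300,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    shrink = [2 ** (levels - 1 - i) for i in range(levels)]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([max(s - 1, 0) for s in shrink])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    init = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg.SetInitialTransform(init, inPlace=True)
    result = sitk.Euler3DTransform(reg.Execute(f_img, m_img))

    # sanity: the aligned images must overlap
    resampled = sitk.Resample(m_img, f_img, result, sitk.sitkLinear, 0.0)
    if np.count_nonzero(sitk.GetArrayViewFromImage(resampled)) == 0 and \
            np.count_nonzero(moving.grid) > 0:
        raise ValueError("registration produced an empty overlap")

    angles = tuple(float(np.rad2deg(a)) for a in result.GetParameters()[:3])
    trans = tuple(float(t) for t in result.GetParameters()[3:6])
    center = tuple(float(c) for c in result.GetCenter())
    return RigidTransform(rotation=angles, translation=trans, center=center)


def apply_rigid(moving: Volume, transform: RigidTransform,
                reference: Volume) -> Volume:
    """Resample ``moving`` through ``transform`` onto ``reference``'s grid."""
    t = sitk.Euler3DTransform()
    t.SetCenter(transform.center)
    t.SetRotation(*[float(np.deg2rad(a)) for a in transform.rotation])
    t.SetTranslation(transform.translation)
    out = sitk.Resample(_to_sitk(moving), _to_sitk(reference), t,
                        sitk.sitkLinear, 0.0)
    grid = np.transpose(sitk.GetArrayFromImage(out), (2, 1, 0)).astype(float)
    return Volume(grid=grid, spacing=reference.spacing,
                  orientation_tag=reference.orientation_tag,
                  modality=moving.modality, patient_id=moving.patient_id)


# --------------------------------------------------------------------------
# skull stripping
# --------------------------------------------------------------------------

def apply_brain_mask(vol: Volume, mask: BrainMask) -> Volume:
    """Zero every voxel outside the brain mask."""
    if mask.grid.shape != vol.grid.shape:
        raise ValueError("brain mask shape does not match volume")
    if not mask.grid.any():
        raise EmptyBrainError("empty brain: mask selects no voxels")
    return vol.with_grid(np.where(mask.grid, vol.grid, 0.0))


def fallback_brain_mask(vol: Volume, *, closing_iterations: int = 2) -> BrainMask:
    """Simple intensity-based brain mask for data without an external one.

    A global two-class (Otsu) threshold separates head tissue from
    background; the largest connected supra-threshold component is kept and
    morphologically closed.  This is a coarse stand-in for a dedicated
    skull-stripping model — acceptable here because the downstream ROI
    preselection is robust to residual non-brain tissue.
    """
    grid = np.asarray(vol.grid, dtype=float)
    if float(grid.max() - grid.min()) < 1e-8:
        raise ValueError("cannot derive a brain mask from a near-constant volume")
    thr = threshold_otsu(grid)
    fg = grid > thr
    if not fg.any():
        raise ValueError("no supra-threshold voxels for the fallback brain mask")
    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("no connected components above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    mask = labels == keep
    if closing_iterations > 0:
        mask = ndimage.binary_closing(mask, iterations=closing_iterations)
        # closing can merge in nothing new outside the head; keep largest CC only
        labels2, n2 = ndimage.label(mask)
        if n2 > 1:
            sizes2 = ndimage.sum_labels(np.ones_like(labels2), labels2,
                                        index=np.arange(1, n2 + 1))
            mask = labels2 == (int(np.argmax(sizes2)) + 1)
    return BrainMask(grid=mask, source="fallback")


# --------------------------------------------------------------------------
# NIfTI round-trip
# --------------------------------------------------------------------------

def save_nifti(vol_or_mask, path) -> None:
    """Write a volume or binary mask with a diagonal (spacing) affine."""
    if isinstance(vol_or_mask, Volume):
        data = np.asarray(vol_or_mask.grid, dtype=np.float32)
        spacing = vol_or_mask.spacing
    else:
        data = np.asarray(vol_or_mask.grid, dtype=np.uint8)
        spacing = (1.0, 1.0, 1.0)
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_nifti(path, *, modality: str = "FLAIR", patient_id: str = "anon",
               orientation_tag: str = SAGITTAL_CODE) -> Volume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(grid=np.asarray(img.dataobj, dtype=float), spacing=spacing,
                  orientation_tag=orientation_tag, modality=modality,
                  patient_id=patient_id)


def load_mask_nifti(path, *, source: str = "external") -> BrainMask:
    img = nib.load(str(path))
    return BrainMask(grid=np.asarray(img.dataobj) > 0, source=source)
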