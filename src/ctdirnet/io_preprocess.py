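"""NIfTI I/O, geometric standardization, and invertible HU normalization.

The preprocessing chain mirrors standard planning-CT conditioning: rigidly
align each CT to a reference, resample everything onto one grid (default
2 x 1.26 x 1.26 mm), center-crop to a fixed dimension (default 136 x 384 x 384),
and map HU to unitless intensities via ``(HU + 1000) / 3000`` (air -> 0,
~2000 HU -> 1; values are not clipped).  Every step records what it did in a
:class:`PreprocessRecord` so that synthetic CTs can be mapped back onto the
original grid by :func:`postprocess`.

Arrays follow the package-wide (z, y, x) axis convention.  Rigid registration
and resampling are delegated to SimpleITK (6-DOF Euler transform,
mean-squares metric, multi-resolution gradient descent); the returned
parameters use a fixed convention documented on :func:`rigid_register`.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import (
    ConsistencyError,
    ConvergenceError,
    DimensionalityError,
    ParameterError,
)
from .grids import CTVolume, NormVolume

DEFAULT_SPACING = (2.0, 1.26, 1.26)      # (dz, dy, dx) mm
DEFAULT_CROP = (136, 384, 384)
DEFAULT_NORM_SHIFT = 1000.0              # HU
DEFAULT_NORM_SCALE = 3000.0              # HU
DEFAULT_FILL_HU = -1000.0                # air


@dataclass
class PreprocessRecord:
    """Invertible bookkeeping of the preprocessing steps applied to one volume."""

    rigid_params: tuple[float, ...] = (0.0,) * 6   # (rz, ry, rx) rad, (tz, ty, tx) mm
    crop_offsets: tuple[int, int, int] = (0, 0, 0)
    original_shape: tuple[int, int, int] = (0, 0, 0)
    pad_fill_hu: float = DEFAULT_FILL_HU
    norm_shift: float = DEFAULT_NORM_SHIFT
    norm_scale: float = DEFAULT_NORM_SCALE

    def __post_init__(self) -> None:
        if any(o < 0 for o in self.crop_offsets):
            raise ParameterError("crop offsets must be >= 0")


def load_preprocess_config(path) -> dict:
    """Read the ``preprocess:`` block of a YAML config into preprocess() kwargs.

    Recognized keys: spacing, crop_shape, norm_shift, norm_scale, fill_hu.
    Missing keys fall back to the package defaults.
    """
    import yaml

    raw = yaml.safe_load(open(path)) or {}
    block = raw.get("preprocess", {})
    return {
        "target_spacing": tuple(block.get("spacing", DEFAULT_SPACING)),
        "crop_shape": tuple(block.get("crop_shape", DEFAULT_CROP)),
        "shift": float(block.get("norm_shift", DEFAULT_NORM_SHIFT)),
        "scale": float(block.get("norm_scale", DEFAULT_NORM_SCALE)),
        "fill_hu": float(block.get("fill_hu", DEFAULT_FILL_HU)),
    }


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path) -> CTVolume:
    """Read a 3-D NIfTI image into the (z, y, x) convention."""
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    return CTVolume(
        np.ascontiguousarray(data.T.astype(np.float64)),
        spacing=tuple(float(z) for z in zooms[::-1]),
        origin=tuple(float(o) for o in origin[::-1]),
    )


def write_volume(volume: CTVolume, path) -> None:
    """Write a CTVolume as NIfTI (affine encodes spacing and origin)."""
    dz, dy, dx = volume.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = volume.origin[::-1]
    nib.save(nib.Nifti1Image(volume.values.T, affine), str(path))


def read_mask(path) -> np.ndarray:
    """Read a binary structure bitmap (any nonzero voxel counts as inside)."""
    return read_volume(path).values > 0.5


def write_mask(mask: np.ndarray, spacing, path) -> None:
    write_volume(CTVolume(np.asarray(mask, dtype=np.float64), spacing), path)


def read_dvf(path):
    """Read a 4-D NIfTI (last axis = 3 components, voxel units) displacement field."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise DimensionalityError(f"{path}: expected (nx, ny, nz, 3) field, got {data.shape}")
    from .grids import DisplacementField

    comps = np.stack([data[..., c].T for c in range(3)])
    zooms = img.header.get_zooms()[:3]
    return DisplacementField(comps, spacing=tuple(float(z) for z in zooms[::-1]))


def write_dvf(dvf, path) -> None:
    dz, dy, dx = dvf.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    data = np.stack([dvf.components[c].T for c in range(3)], axis=-1)
    nib.save(nib.Nifti1Image(data, affine), str(path))


# ---------------------------------------------------------------------------
# rigid registration and resampling (SimpleITK backend)


def _to_sitk(volume: CTVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(volume.values.astype(np.float32))
    img.SetSpacing(tuple(volume.spacing[::-1]))      # sitk wants (dx, dy, dz)
    img.SetOrigin(tuple(volume.origin[::-1]))
    return img


def _grid_center_xyz(shape, spacing, origin=(0.0, 0.0, 0.0)):
    """Physical center (x, y, z) of a grid given (z, y, x) shape/spacing/origin."""
    czyx = [o + s * (n - 1) / 2.0 for o, s, n in zip(origin, spacing, shape)]
    return tuple(czyx[::-1])


def _euler_from_params(rigid_params, center_xyz) -> sitk.Euler3DTransform:
    rz, ry, rx, tz, ty, tx = rigid_params
    t = sitk.Euler3DTransform()
    t.SetCenter(center_xyz)
    t.SetRotation(rx, ry, rz)
    t.SetTranslation((tx, ty, tz))
    return t


def rigid_register(moving: CTVolume, reference: CTVolume,
                   max_iters: int = 200) -> tuple[float, ...]:
    """Estimate the 6-DOF transform aligning ``moving`` to ``reference``.

    Minimizes the mean-squared HU difference with a 3-level multi-resolution
    gradient-descent scheme (full sampling, hence deterministic).  Returns
    ``(rz, ry, rx, tz, ty, tx)`` — Euler rotations (rad) and translations
    (mm) of the transform mapping reference-space physical points to
    moving-space points, with the rotation centered on the reference grid's
    physical center.  Feed these to :func:`resample` to bring ``moving`` onto
    the reference grid.
    """
    if moving.values.size == 0 or reference.values.size == 0:
        raise ParameterError("cannot register empty volumes")
    fixed = _to_sitk(reference)
    mov = _to_sitk(moving)

    initial = sitk.CenteredTransformInitializer(
        fixed, mov, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-5, numberOfIterations=max_iters,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    levels = [4, 2, 1]
    reg.SetShrinkFactorsPerLevel(levels)
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(initial, inPlace=False)
    try:
        final = reg.Execute(fixed, mov)
    except RuntimeError as exc:       # no overlap after initialization
        raise ConvergenceError(f"rigid registration failed: {exc}") from exc

    final = final.Downcast()
    if final.GetName() == "CompositeTransform":
        final = final.GetNthTransform(0).Downcast()
    euler = sitk.Euler3DTransform(final)
    # re-center on the reference grid center: t' = t + (I - R)(c - c')
    c = np.array(euler.GetCenter())
    cp = np.array(_grid_center_xyz(reference.shape, reference.spacing, reference.origin))
    rmat = np.array(euler.GetMatrix()).reshape(3, 3)
    t = np.array(euler.GetTranslation())
    t_new = t + (c - cp) - rmat @ (c - cp)
    rx, ry, rz = euler.GetAngleX(), euler.GetAngleY(), euler.GetAngleZ()
    return (float(rz), float(ry), float(rx),
            float(t_new[2]), float(t_new[1]), float(t_new[0]))


def resample(volume: CTVolume, rigid_params=None, target_spacing=DEFAULT_SPACING,
             target_shape=None, fill_hu: float = DEFAULT_FILL_HU,
             target_origin=(0.0, 0.0, 0.0)) -> CTVolume:
    """Resample ``volume`` onto a target grid under an optional rigid transform.

    Trilinear interpolation; out-of-field voxels receive ``fill_hu``.  The
    rigid parameters follow the :func:`rigid_register` convention (rotation
    centered on the *target* grid's physical center).
    """
    if any(s <= 0 for s in target_spacing):
        raise ParameterError(f"target spacing must be positive, got {target_spacing}")
    if target_shape is None:
        target_shape = volume.shape
    target_shape = tuple(int(n) for n in target_shape)

    if rigid_params is None:
        rigid_params = (0.0,) * 6
    center = _grid_center_xyz(target_shape, target_spacing, target_origin)
    transform = _euler_from_params(rigid_params, center)

    img = _to_sitk(volume)
    out = sitk.Resample(
        img,
        size=tuple(int(n) for n in target_shape[::-1]),
        transform=transform,
        interpolator=sitk.sitkLinear,
        outputOrigin=tuple(float(o) for o in target_origin[::-1]),
        outputSpacing=tuple(float(s) for s in target_spacing[::-1]),
        outputDirection=(1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0),
        defaultPixelValue=float(fill_hu),
    )
    return CTVolume(sitk.GetArrayFromImage(out).astype(np.float64),
                    spacing=tuple(target_spacing), origin=tuple(target_origin))


# ---------------------------------------------------------------------------
# cropping and normalization


def center_crop(volume: CTVolume, target_shape=DEFAULT_CROP,
                fill_hu: float = DEFAULT_FILL_HU) -> tuple[CTVolume, PreprocessRecord]:
    """Centered crop to ``target_shape``.

    When the size difference along an axis is odd the extra voxel is kept on
    the high-index side (i.e. the crop starts at ``(n - t) // 2``).
    """
    target_shape = tuple(int(n) for n in target_shape)
    if any(t > n for t, n in zip(target_shape, volume.shape)):
        raise ParameterError(
            f"crop shape {target_shape} exceeds volume shape {volume.shape}"
        )
    if any(t < 1 for t in target_shape):
        raise ParameterError("crop shape components must be >= 1")
    offsets = tuple((n - t) // 2 for n, t in zip(volume.shape, target_shape))
    sl = tuple(slice(o, o + t) for o, t in zip(offsets, target_shape))
    record = PreprocessRecord(
        crop_offsets=offsets, original_shape=volume.shape, pad_fill_hu=fill_hu
    )
    return CTVolume(volume.values[sl].copy(), volume.spacing, volume.origin), record


def normalize(volume: CTVolume, shift: float = DEFAULT_NORM_SHIFT,
              scale: float = DEFAULT_NORM_SCALE) -> NormVolume:
    """Map HU to unitless intensities: ``v = (HU + shift) / scale`` (no clipping)."""
    return NormVolume((volume.values + shift) / scale, volume.spacing, volume.origin)


def denormalize(norm: NormVolume, shift: float = DEFAULT_NORM_SHIFT,
                scale: float = DEFAULT_NORM_SCALE) -> CTVolume:
    """Exact inverse of :func:`normalize`: ``HU = v * scale - shift``."""
    return CTVolume(norm.values * scale - shift, norm.spacing, norm.origin)


def preprocess(volume: CTVolume, reference: CTVolume | None = None,
               target_spacing=DEFAULT_SPACING, crop_shape=DEFAULT_CROP,
               shift: float = DEFAULT_NORM_SHIFT, scale: float = DEFAULT_NORM_SCALE,
               fill_hu: float = DEFAULT_FILL_HU, resample_shape=None,
               artifact_reduction=None) -> tuple[NormVolume, PreprocessRecord]:
    """Full chain: rigid align (if a reference is given), resample, crop, normalize.

    ``artifact_reduction`` is an optional CTVolume -> CTVolume callable applied
    first (hook for scanner-specific corrections such as metal-artifact
    reduction); by default nothing is applied.
    """
    rigid = (0.0,) * 6
    work = volume if artifact_reduction is None else artifact_reduction(volume)
    volume = work
    if reference is not None:
        rigid = rigid_register(volume, reference)
        work = resample(volume, rigid, target_spacing,
                        resample_shape or reference.shape, fill_hu)
    elif resample_shape is not None or tuple(target_spacing) != volume.spacing:
        work = resample(volume, None, target_spacing,
                        resample_shape or volume.shape, fill_hu)
    cropped, record = center_crop(work, crop_shape, fill_hu)
    record.rigid_params = tuple(rigid)
    record.norm_shift = shift
    record.norm_scale = scale
    return normalize(cropped, shift, scale), record


def postprocess(sct_norm: NormVolume, record: PreprocessRecord) -> CTVolume:
    """Map a synthetic CT back to HU on the pre-crop grid.

    Denormalizes and pads the cropped region back to ``record.original_shape``
    with ``record.pad_fill_hu``.  The rigid alignment is *not* inverted: the
    synthetic CT is defined on the reference-aligned grid of its initial CT.
    """
    hu = denormalize(sct_norm, record.norm_shift, record.norm_scale)
    cropped_shape = hu.shape
    if any(o + c > n for o, c, n in
           zip(record.crop_offsets, cropped_shape, record.original_shape)):
        raise ConsistencyError(
            f"record (offsets {record.crop_offsets}, original {record.original_shape}) "
            f"inconsistent with volume shape {cropped_shape}"
        )
    out = np.full(record.original_shape, record.pad_fill_hu, dtype=np.float64)
    sl = tuple(slice(o, o + c) for o, c in zip(record.crop_offsets, cropped_shape))
    out[sl] = hu.values
    return CTVolume(out, hu.spacing, hu.origin)
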