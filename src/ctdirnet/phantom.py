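"""Synthetic thorax phantoms with known ground-truth deformations.

Generates desk-scale stand-ins for inter-fraction thoracic CT pairs: a
soft-tissue body ellipsoid containing two lungs, a spherical tumor (the CTV)
inside the right lung, a vertebral column with spinal cord, an esophageal tube
and a cardiac ellipsoid, all painted at standard tissue Hounsfield levels and
corrupted by additive Gaussian noise.  Smooth fold-free displacement fields
emulate inter-fraction anatomy change; warping the phantom by such a field
yields a verification image with exactly known correspondence.  Synthetic dose
grids (sums of anisotropic Gaussian beam kernels) feed the dosimetric
evaluation stack.

Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError, ParameterError
from .grids import CTVolume, DisplacementField, DoseGrid, StructureSet, require_same_grid
from .transform_losses import warp

DEFAULT_HU = {"air": -1000.0, "lung": -800.0, "soft": 40.0, "bone": 700.0}

STRUCTURE_NAMES = ("CTV", "lung_L", "lung_R", "heart", "cord", "esophagus")


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of the synthetic thorax."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)   # mm
    hu_levels: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HU))
    tumor_radius: float = 8.0                               # mm
    noise_sigma: float = 5.0                                # HU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.tumor_radius <= 0:
            raise ParameterError("tumor_radius must be positive")
        missing = set(DEFAULT_HU) - set(self.hu_levels)
        if missing:
            raise ParameterError(f"hu_levels missing tissues: {sorted(missing)}")


@dataclass
class DeformationSpec:
    """Parameters of the random smooth deformation."""

    max_displacement: float = 4.0    # voxels, peak Euclidean norm
    n_modes: int = 3                 # low-frequency sinusoidal components
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_displacement < 0:
            raise ParameterError("max_displacement must be >= 0")
        if self.n_modes < 1:
            raise ParameterError("n_modes must be >= 1")


# ---------------------------------------------------------------------------


def _normalized_coords(shape):
    """Per-axis coordinates scaled to [-1, 1] over the grid."""
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(coords, center, semiaxes) -> np.ndarray:
    z, y, x = coords
    cz, cy, cx = center
    az, ay, ax_ = semiaxes
    return ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax_) ** 2 <= 1.0


def _cylinder_z(coords, center_yx, radius_yx, z_extent=(-0.9, 0.9)) -> np.ndarray:
    z, y, x = coords
    cy, cx = center_yx
    ry, rx = radius_yx
    return (((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0) & \
        (z >= z_extent[0]) & (z <= z_extent[1])


def make_thorax_phantom(spec: PhantomSpec = PhantomSpec()) -> tuple[CTVolume, StructureSet]:
    """Build the thorax phantom and its structure set.

    Tissue regions are painted by priority (later wins): body soft tissue,
    lungs, heart, esophagus, vertebra, cord, tumor.  Structure bitmaps are
    derived from the final label map, so they are mutually disjoint.
    """
    coords = _normalized_coords(spec.shape)
    hu = spec.hu_levels

    body = _ellipsoid(coords, (0, 0, 0), (0.97, 0.82, 0.90))
    lung_l = _ellipsoid(coords, (0.0, -0.05, -0.42), (0.62, 0.48, 0.30))
    lung_r = _ellipsoid(coords, (0.0, -0.05, 0.42), (0.62, 0.48, 0.30))
    heart = _ellipsoid(coords, (0.05, 0.12, -0.10), (0.30, 0.28, 0.24))
    esophagus = _cylinder_z(coords, (0.30, 0.02), (0.09, 0.09))
    vertebra = _cylinder_z(coords, (0.55, 0.0), (0.17, 0.16))
    cord = _cylinder_z(coords, (0.55, 0.0), (0.10, 0.10))

    # tumor: sphere of the requested physical radius inside the right lung
    z, y, x = coords
    tumor_center = (0.10, -0.05, 0.42)
    half_extent = [sp * (n - 1) / 2.0 for sp, n in zip(spec.spacing, spec.shape)]
    dist2 = sum(((c - cc) * h) ** 2 for c, cc, h in zip(coords, tumor_center, half_extent))
    tumor = dist2 <= spec.tumor_radius ** 2

    lung_l &= body & ~heart & ~vertebra
    lung_r &= body & ~heart & ~vertebra
    tumor &= lung_r
    lung_l &= ~tumor
    lung_r &= ~tumor
    heart &= body & ~vertebra
    esophagus &= body & ~vertebra & ~heart
    cord &= vertebra

    values = np.full(spec.shape, hu["air"])
    values[body] = hu["soft"]
    values[lung_l | lung_r] = hu["lung"]
    values[heart] = hu["soft"]
    values[esophagus] = hu["soft"]
    values[vertebra & body] = hu["bone"]
    values[cord] = hu["soft"]
    values[tumor] = hu["soft"]

    masks = {
        "CTV": tumor,
        "lung_L": lung_l,
        "lung_R": lung_r,
        "heart": heart,
        "cord": cord,
        "esophagus": esophagus,
    }
    for name, mask in masks.items():
        if not mask.any():
            raise GenerationError(
                f"structure {name!r} is empty at shape {spec.shape}; "
                "increase the grid size or adjust the geometry"
            )

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    return CTVolume(values, spec.spacing), StructureSet(masks, spacing=spec.spacing)


def make_smooth_dvf(shape, dspec: DeformationSpec = DeformationSpec()) -> DisplacementField:
    """A random smooth fold-free displacement field, zero on a 2-voxel boundary shell.

    Superposes ``n_modes`` low-frequency sinusoidal modes per component, tapers
    them to zero over the outer 6 voxels (exactly zero in the outermost 2), and
    rescales so the peak Euclidean displacement equals ``max_displacement``.
    Raises :class:`GenerationError` if the requested amplitude would fold the
    grid (non-positive Jacobian) — low frequencies and moderate amplitudes
    never do.
    """
    shape = tuple(int(n) for n in shape)
    if any(n < 8 for n in shape):
        raise ParameterError(f"shape must be at least (8, 8, 8), got {shape}")
    if dspec.max_displacement == 0:
        return DisplacementField(np.zeros((3,) + shape))

    rng = np.random.default_rng(dspec.seed)
    # per-axis coordinate t in [0, 1] over the interior (indices 2 .. n-3);
    # the sine envelope sin(pi t) vanishes there, leaving the outer 2-voxel
    # shell exactly zero, and its gentle slope keeps the field fold-free
    interior = []
    for n in shape:
        t = (np.arange(n, dtype=float) - 2.0) / (n - 5.0)
        interior.append(np.clip(t, 0.0, 1.0))
    envelopes = [np.sin(np.pi * t) for t in interior]

    raw = np.zeros((3,) + shape)
    for _ in range(dspec.n_modes):
        for c in range(3):
            freq = rng.uniform(0.25, 0.5, size=3)      # low-frequency modulation
            phase = rng.uniform(0, 2 * np.pi, size=3)
            amp = rng.uniform(0.3, 1.0)
            mode = amp * np.ones(shape)
            for ax in range(3):
                prof = envelopes[ax] * np.cos(
                    2 * np.pi * freq[ax] * interior[ax] + phase[ax]
                )
                w_shape = [1, 1, 1]
                w_shape[ax] = shape[ax]
                mode = mode * prof.reshape(w_shape)
            raw[c] += mode
    for ax, n in enumerate(shape):
        zero = (np.arange(n) < 2) | (np.arange(n) > n - 3)
        sl = [slice(None)] * 4
        sl[1 + ax] = zero
        raw[tuple(sl)] = 0.0

    mag = np.sqrt((raw ** 2).sum(axis=0)).max()
    if mag == 0:
        raise GenerationError("degenerate deformation modes (all zero)")
    field = raw * (dspec.max_displacement / mag)

    # fold check: finite-difference Jacobian of (identity + field)
    jac = np.zeros(tuple(n - 1 for n in shape) + (3, 3))
    crop = tuple(slice(0, n - 1) for n in shape)
    for c in range(3):
        for ax in range(3):
            d = np.diff(field[c], axis=ax)[tuple(
                sl if a == ax else crop[a] for a, sl in enumerate(crop)
            )]
            jac[..., c, ax] = d
    jac += np.eye(3)
    if np.linalg.det(jac).min() <= 0:
        raise GenerationError(
            f"max_displacement={dspec.max_displacement} folds the grid at shape {shape}; "
            "reduce the amplitude or increase the grid"
        )
    return DisplacementField(field)


def make_pair(ct: CTVolume, structures: StructureSet,
              dvf_true: DisplacementField) -> tuple[CTVolume, CTVolume, StructureSet]:
    """Derive an (iCT, vCT) pair from one phantom and a known deformation.

    ``iCT`` is the phantom itself; ``vCT`` and its structures are the phantom
    warped by ``dvf_true`` (bitmaps thresholded at 0.5), so the deformation
    relating the pair is known exactly.
    """
    require_same_grid(ct, dvf_true, "phantom and deformation")
    if structures.names and structures[structures.names[0]].shape != ct.shape:
        raise ParameterError("structures do not match the phantom grid")
    vct_values = warp(ct.values, dvf_true)
    vct = CTVolume(vct_values, ct.spacing, ct.origin)
    vstructs = StructureSet(
        {name: warp(structures[name], dvf_true) for name in structures.names},
        spacing=structures.spacing,
    )
    return ct, vct, vstructs


@dataclass
class GaussianBeam:
    """One anisotropic Gaussian dose kernel: peak dose (Gy) at ``center_mm``."""

    center_mm: tuple[float, float, float]     # (z, y, x) mm from grid corner
    sigma_mm: tuple[float, float, float]      # (z, y, x) mm
    weight: float = 1.0                       # peak dose contribution, Gy

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma_mm):
            raise ParameterError("beam sigma_mm must be positive")
        if self.weight < 0:
            raise ParameterError("beam weight must be >= 0")


def make_dose_grid(shape, spacing, beams: list[GaussianBeam],
                   seed: int = 0, noise_sigma: float = 0.0,
                   prescription: float | None = None) -> DoseGrid:
    """Sum of Gaussian beam kernels, optionally rescaled to a prescription max.

    Without rescaling the dose is linear in the beam weights and a single
    beam's maximum equals its weight.  ``noise_sigma`` (Gy) adds seeded
    Gaussian noise, clipped at zero dose.
    """
    if not beams:
        raise ParameterError("at least one beam is required")
    shape = tuple(int(n) for n in shape)
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                        indexing="ij")
    dose = np.zeros(shape)
    for beam in beams:
        expo = sum(((g - c) / s) ** 2 for g, c, s in
                   zip(grids, beam.center_mm, beam.sigma_mm))
        dose += beam.weight * np.exp(-0.5 * expo)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        dose = np.maximum(dose + rng.normal(0, noise_sigma, size=shape), 0.0)
    if prescription is not None:
        peak = dose.max()
        if peak <= 0:
            raise ParameterError("cannot rescale an all-zero dose grid")
        dose *= prescription / peak
    return DoseGrid(dose, spacing)
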