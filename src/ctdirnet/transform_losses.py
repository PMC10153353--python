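"""Spatial transformer, registration losses, and the random-mask augmentation.

The warp is a *backward* trilinear sampler: ``output(p) = input(p + g(p))`` with
``g`` in voxel units, clamping sample coordinates to the grid border.  Binary
masks are warped as floats and re-thresholded at 0.5.

Three loss terms drive training:

* ``wmae_loss`` — per-voxel mean absolute intensity error, weighted by the
  reference image's normalized intensity so that dense tissue (bone) counts
  more than air.  The weight is ``clamp(iCT_norm, w_min, 1)`` with a small
  floor ``w_min`` so that air regions still contribute.
* ``smooth_loss`` — mean squared forward-difference gradient of the
  displacement field, discouraging physically implausible fields.
* ``structure_ssim_loss`` — one minus the mean structural similarity between
  corresponding structure bitmaps, pulling propagated contours toward the
  reference ones.

``combined_loss`` assembles the two published objectives: the intensity-only
variant (``wMAE``) and the intensity + structure variant (``M+S``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .errors import ConsistencyError, ParameterError
from .grids import DisplacementField, NormVolume, StructureSet

VARIANTS = ("wMAE", "M+S")


@dataclass
class LossWeights:
    """Weights of the combined objective.

    alpha: smoothness weight; beta: structure-SSIM weight; w_min: floor of the
    per-voxel intensity weight (unitless, in [0, 1]).
    """

    alpha: float = 0.01
    beta: float = 0.1
    w_min: float = 0.05

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ParameterError("alpha and beta must be non-negative")
        if not 0 <= self.w_min <= 1:
            raise ParameterError("w_min must lie in [0, 1]")


@dataclass
class SSIMParams:
    """Stabilizer constants of the structural similarity index.

    Defaults follow the standard choice C1 = (0.01 R)^2, C2 = (0.03 R)^2 with
    dynamic range R = 1 (binary bitmaps and normalized volumes).
    """

    c1: float = 1e-4
    c2: float = 9e-4
    dynamic_range: float = 1.0

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0:
            raise ParameterError("SSIM stabilizers must be positive")

    @classmethod
    def for_dynamic_range(cls, r: float) -> "SSIMParams":
        return cls(c1=(0.01 * r) ** 2, c2=(0.03 * r) ** 2, dynamic_range=r)


@dataclass
class MaskRecord:
    """Location of one random training mask cube (``size == 0`` means no mask)."""

    corner: tuple[int, int, int]
    size: int


# ---------------------------------------------------------------------------
# warping


def _dvf_components(dvf) -> np.ndarray:
    if isinstance(dvf, DisplacementField):
        return dvf.components
    return np.asarray(dvf)


def warp(volume, dvf):
    """Warp a volume or binary mask by a displacement field.

    Accepts a :class:`NormVolume`, a float array, or a boolean array (bitmap);
    returns the same type.  Bitmaps are interpolated as floats then
    thresholded at 0.5.
    """
    g = _dvf_components(dvf)
    if isinstance(volume, NormVolume):
        if volume.shape != g.shape[1:]:
            raise ConsistencyError(
                f"volume {volume.shape} vs field {g.shape[1:]}"
            )
        out = ad.warp_volume(volume.values, ad.Tensor(g)).data
        return NormVolume(out, volume.spacing, volume.origin)
    arr = np.asarray(volume)
    if arr.shape != g.shape[1:]:
        raise ConsistencyError(f"volume {arr.shape} vs field {g.shape[1:]}")
    if arr.dtype == bool:
        soft = ad.warp_volume(arr.astype(np.float64), ad.Tensor(g)).data
        return soft > 0.5
    return ad.warp_volume(arr, ad.Tensor(g.astype(arr.dtype, copy=False))).data


def warp_structures(structs: StructureSet, dvf) -> StructureSet:
    """Propagate every bitmap of a structure set through the same field."""
    return StructureSet(
        {name: warp(structs[name], dvf) for name in structs.names},
        spacing=structs.spacing,
    )


# ---------------------------------------------------------------------------
# losses (scalar frontends + autodiff internals)


def _values(x) -> np.ndarray:
    if isinstance(x, NormVolume):
        return x.values
    return np.asarray(x, dtype=np.float64)


def intensity_weights(ict, w_min: float) -> np.ndarray:
    """Per-voxel wMAE weights: the reference normalized intensity, floored."""
    return np.clip(_values(ict), w_min, 1.0)


def _wmae_tensor(ict: np.ndarray, sct: ad.Tensor, w_min: float) -> ad.Tensor:
    w = np.clip(ict, w_min, 1.0).astype(sct.data.dtype)
    diff = ad.absolute(ad.sub(ad.Tensor(ict.astype(sct.data.dtype)), sct))
    return ad.mean(ad.mul(ad.Tensor(w), diff))


def wmae_loss(ict, sct, weights: LossWeights = LossWeights()) -> float:
    """HU-weighted mean absolute error between two normalized volumes."""
    a, b = _values(ict), _values(sct)
    if a.shape != b.shape:
        raise ConsistencyError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(_wmae_tensor(a, ad.Tensor(b), weights.w_min).item())


def smooth_loss(dvf) -> float:
    """Mean squared forward-difference gradient of the field (see autodiff.smoothness)."""
    return float(ad.smoothness(ad.Tensor(_dvf_components(dvf))).item())


def ssim(x, y, params: SSIMParams = SSIMParams()) -> float:
    """Global structural similarity index of two 3-D grids (1 = identical)."""
    a = np.asarray(x, dtype=np.float64)
    b = np.asarray(y, dtype=np.float64)
    if a.shape != b.shape:
        raise ConsistencyError(f"shape mismatch {a.shape} vs {b.shape}")
    mu_x, mu_y = a.mean(), b.mean()
    var_x = ((a - mu_x) ** 2).mean()
    var_y = ((b - mu_y) ** 2).mean()
    cov = ((a - mu_x) * (b - mu_y)).mean()
    num = (2 * mu_x * mu_y + params.c1) * (2 * cov + params.c2)
    den = (mu_x ** 2 + mu_y ** 2 + params.c1) * (var_x + var_y + params.c2)
    return float(num / den)


def _ssim_tensor(x: ad.Tensor, y: np.ndarray, params: SSIMParams) -> ad.Tensor:
    """Differentiable global SSIM of a tensor against a constant grid."""
    y = y.astype(x.data.dtype)
    mu_x = ad.mean(x)
    mu_y = float(y.mean())
    ex2 = ad.mean(ad.mul(x, x))
    var_x = ad.sub(ex2, ad.mul(mu_x, mu_x))
    var_y = float(((y - mu_y) ** 2).mean())
    exy = ad.mean(ad.mul(x, ad.Tensor(y)))
    cov = ad.sub(exy, ad.mul(mu_x, mu_y))
    num = ad.mul(ad.add(ad.mul(ad.mul(mu_x, mu_y), 2.0), params.c1),
                 ad.add(ad.mul(cov, 2.0), params.c2))
    den = ad.mul(ad.add(ad.add(ad.mul(mu_x, mu_x), mu_y ** 2), params.c1),
                 ad.add(ad.add(var_x, var_y), params.c2))
    return ad.div(num, den)


def structure_ssim_loss(structs_i: StructureSet, structs_s: StructureSet,
                        params: SSIMParams = SSIMParams()) -> float:
    """1 - mean SSIM over corresponding structure bitmaps (0 iff all identical)."""
    if set(structs_i.names) != set(structs_s.names):
        raise ConsistencyError(
            f"structure names differ: {sorted(structs_i.names)} vs {sorted(structs_s.names)}"
        )
    vals = [ssim(structs_i[n].astype(float), structs_s[n].astype(float), params)
            for n in structs_i.names]
    return float(1.0 - np.mean(vals))


def combined_loss(ict, sct, dvf, structs_i: StructureSet | None = None,
                  structs_s: StructureSet | None = None,
                  weights: LossWeights = LossWeights(),
                  variant: str = "wMAE",
                  ssim_params: SSIMParams = SSIMParams()) -> float:
    """The full objective: wMAE + alpha*smooth (+ beta*structure term for M+S)."""
    if variant not in VARIANTS:
        raise ParameterError(f"variant must be one of {VARIANTS}, got {variant!r}")
    loss = wmae_loss(ict, sct, weights) + weights.alpha * smooth_loss(dvf)
    if variant == "M+S":
        if structs_i is None or structs_s is None:
            raise ParameterError("the M+S variant requires both structure sets")
        loss += weights.beta * structure_ssim_loss(structs_i, structs_s, ssim_params)
    return float(loss)


def training_objective(ict: np.ndarray, vct: np.ndarray, dvf: ad.Tensor,
                       struct_masks_i: dict[str, np.ndarray] | None = None,
                       struct_masks_v: dict[str, np.ndarray] | None = None,
                       weights: LossWeights = LossWeights(),
                       variant: str = "wMAE",
                       ssim_params: SSIMParams = SSIMParams()):
    """Differentiable objective as a function of the displacement field.

    Warps ``vct`` (and, for M+S, each moving structure bitmap as a float, so
    the structure term stays differentiable) by ``dvf`` and evaluates the
    combined loss against ``ict`` (and the reference bitmaps).  Returns
    ``(loss_tensor, term_dict)`` where the terms are plain floats.
    """
    if variant not in VARIANTS:
        raise ParameterError(f"variant must be one of {VARIANTS}, got {variant!r}")
    sct = ad.warp_volume(vct, dvf)
    l_wmae = _wmae_tensor(np.asarray(ict), sct, weights.w_min)
    l_smooth = ad.smoothness(dvf)
    loss = ad.add(l_wmae, ad.mul(l_smooth, weights.alpha))
    terms = {"wmae": float(l_wmae.item()), "smooth": float(l_smooth.item())}
    if variant == "M+S":
        if struct_masks_i is None or struct_masks_v is None:
            raise ParameterError("the M+S variant requires structure bitmaps")
        if set(struct_masks_i) != set(struct_masks_v):
            raise ConsistencyError("structure names differ between the pair")
        ssim_sum = None
        for name in struct_masks_i:
            soft = ad.warp_volume(np.asarray(struct_masks_v[name], dtype=vct.dtype), dvf)
            s = _ssim_tensor(soft, np.asarray(struct_masks_i[name], dtype=float), ssim_params)
            ssim_sum = s if ssim_sum is None else ad.add(ssim_sum, s)
        k = len(struct_masks_i)
        l_struct = ad.sub(1.0, ad.div(ssim_sum, float(k)))
        loss = ad.add(loss, ad.mul(l_struct, weights.beta))
        terms["structure_ssim"] = float(l_struct.item())
    terms["total"] = float(loss.item())
    return loss, terms


# ---------------------------------------------------------------------------
# random-mask augmentation


def apply_random_mask(ict, vct, m: int, rng: np.random.Generator):
    """Zero out one randomly placed m^3 cube at the same location in both volumes.

    The cube corner is uniform over all positions that keep the cube inside the
    grid.  ``m == 0`` returns the inputs unchanged.  Returns
    ``(masked_ict, masked_vct, MaskRecord)``.
    """
    a, b = _values(ict), _values(vct)
    if a.shape != b.shape:
        raise ConsistencyError(f"pair shape mismatch {a.shape} vs {b.shape}")
    if m < 0 or (m > 0 and m > min(a.shape)):
        raise ParameterError(f"mask size {m} does not fit inside shape {a.shape}")
    if m == 0:
        return ict, vct, MaskRecord((0, 0, 0), 0)
    corner = tuple(int(rng.integers(0, n - m + 1)) for n in a.shape)
    sl = tuple(slice(c, c + m) for c in corner)
    am, bm = a.copy(), b.copy()
    am[sl] = 0.0
    bm[sl] = 0.0
    record = MaskRecord(corner, m)
    if isinstance(ict, NormVolume):
        am = NormVolume(am, ict.spacing, ict.origin)
    if isinstance(vct, NormVolume):
        bm = NormVolume(bm, vct.spacing, vct.origin)
    return am, bm, record
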