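"""Image-quality, structure-agreement, and dosimetric evaluation.

Implements the metrics used to judge synthetic CTs in adaptive radiotherapy:

* MAE and the per-voxel absolute CT-number-difference volume histogram (CDVH:
  fraction of voxels whose |dHU| strictly exceeds each threshold);
* structure agreement via global SSIM and the Dice similarity coefficient;
* cumulative dose-volume histograms with the clinical indices D95, D5, Dmean,
  Dmax and V5;
* 3-D gamma analysis with global dose normalization and a low-dose exclusion
  threshold (the usual reading of criteria like "3%/3mm/10%");
* the paired Student's t-test for per-patient index comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import ConsistencyError, DegenerateInputError, ParameterError
from .grids import CTVolume, DoseGrid, StructureSet, require_same_grid
from .transform_losses import SSIMParams, ssim


@dataclass
class CDVHCurve:
    """Exceedance curve: fraction of voxels with |dHU| > threshold."""

    thresholds: np.ndarray        # HU, ascending, >= 0
    exceed_fraction: np.ndarray   # in [0, 1], non-increasing

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.exceed_fraction = np.asarray(self.exceed_fraction, dtype=float)


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram: volume fraction receiving >= dose."""

    dose_axis: np.ndarray         # Gy, ascending from 0
    volume_fraction: np.ndarray   # in [0, 1], non-increasing, starts at 1


@dataclass
class GammaResult:
    """Per-voxel gamma values (NaN where excluded) and the passing rate."""

    gamma_map: np.ndarray
    passing_rate: float
    criteria: tuple[float, float, float]    # (dose %, DTA mm, threshold %)


def _vol_values(x) -> np.ndarray:
    if isinstance(x, CTVolume):
        return x.values
    return np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# image quality


def mae_hu(ict, sct, mask: np.ndarray | None = None) -> float:
    """Mean absolute HU difference, optionally restricted to a mask."""
    a, b = _vol_values(ict), _vol_values(sct)
    if a.shape != b.shape:
        raise ConsistencyError(f"shape mismatch {a.shape} vs {b.shape}")
    diff = np.abs(a - b)
    if mask is None:
        return float(diff.mean())
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != a.shape:
        raise ConsistencyError("mask grid differs from the volumes")
    if not mask.any():
        raise ParameterError("mask is empty")
    return float(diff[mask].mean())


def cdvh(ict, sct, thresholds, mask: np.ndarray | None = None) -> CDVHCurve:
    """CDVH with the strict ``>`` convention (0 at the maximum |dHU|)."""
    a, b = _vol_values(ict), _vol_values(sct)
    if a.shape != b.shape:
        raise ConsistencyError(f"shape mismatch {a.shape} vs {b.shape}")
    t = np.asarray(thresholds, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) < 0) or np.any(t < 0):
        raise ParameterError("thresholds must be a non-negative ascending 1-D grid")
    diff = np.abs(a - b)
    if mask is not None:
        diff = diff[np.asarray(mask, dtype=bool)]
    n = diff.size
    frac = np.array([(diff > ti).sum() / n for ti in t])
    return CDVHCurve(t, frac)


def cdvh_quantile(curve: CDVHCurve, fraction: float) -> float:
    """Smallest threshold at which the exceedance fraction drops to ``fraction``.

    Linear interpolation between tabulated grid points; e.g. fraction 0.05
    gives the |dHU| level exceeded by only 5% of voxels.
    """
    if not 0 < fraction < 1:
        raise ParameterError("fraction must lie strictly between 0 and 1")
    t, f = curve.thresholds, curve.exceed_fraction
    if f[0] <= fraction:
        return float(t[0])
    if f[-1] > fraction:
        return float(t[-1])
    idx = int(np.argmax(f <= fraction))          # first grid point at/below fraction
    t0, t1, f0, f1 = t[idx - 1], t[idx], f[idx - 1], f[idx]
    if f0 == f1:
        return float(t1)
    return float(t0 + (t1 - t0) * (f0 - fraction) / (f0 - f1))


# ---------------------------------------------------------------------------
# structures


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); two empty masks give 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ConsistencyError(f"shape mismatch {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        warnings.warn("DSC of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / (sa + sb))


def structure_report(structs_truth: StructureSet, structs_prop: StructureSet,
                     params: SSIMParams = SSIMParams()) -> pd.DataFrame:
    """Per-structure SSIM and DSC plus an aggregate row labelled 'average'.

    The aggregate SSIM/DSC are arithmetic means over structures; their
    standard deviations land in the ``ssim_sd`` / ``dsc_sd`` columns of that
    row (NaN elsewhere).
    """
    if set(structs_truth.names) != set(structs_prop.names):
        raise ConsistencyError(
            f"structure names differ: {sorted(structs_truth.names)} vs "
            f"{sorted(structs_prop.names)}"
        )
    rows = []
    for name in structs_truth.names:
        rows.append({
            "structure": name,
            "ssim": ssim(structs_truth[name].astype(float),
                         structs_prop[name].astype(float), params),
            "dsc": dsc(structs_truth[name], structs_prop[name]),
            "ssim_sd": np.nan,
            "dsc_sd": np.nan,
        })
    ssims = [r["ssim"] for r in rows]
    dscs = [r["dsc"] for r in rows]
    rows.append({
        "structure": "average",
        "ssim": float(np.mean(ssims)),
        "dsc": float(np.mean(dscs)),
        "ssim_sd": float(np.std(ssims)),
        "dsc_sd": float(np.std(dscs)),
    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dose


def dvh(dose: DoseGrid, mask: np.ndarray, bin_width: float = 0.05) -> DVHCurve:
    """Cumulative DVH of a structure: fraction of its volume receiving >= d."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.shape:
        raise ConsistencyError("mask grid differs from the dose grid")
    if not mask.any():
        raise ParameterError("mask is empty")
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    d = dose.values[mask]
    top = max(float(d.max()), bin_width)
    axis = np.arange(0.0, top + 2 * bin_width, bin_width)
    frac = np.array([(d >= x).sum() / d.size for x in axis])
    return DVHCurve(axis, frac)


def dvh_index(dose: DoseGrid, mask: np.ndarray, kind: str,
              bin_width: float = 0.05) -> float:
    """Clinical DVH indices.

    D95/D5: minimum dose (Gy) covering the hottest 95%/5% of the structure
    (inverse of the cumulative DVH, linearly interpolated); Dmean/Dmax: mean
    and maximum dose over the structure (Gy); V5: percentage of the structure
    receiving at least 5 Gy.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.shape:
        raise ConsistencyError("mask grid differs from the dose grid")
    if not mask.any():
        raise ParameterError("mask is empty")
    d = dose.values[mask]
    kind = kind.strip()
    if kind == "Dmean":
        return float(d.mean())
    if kind == "Dmax":
        return float(d.max())
    if kind == "V5":
        return float(100.0 * (d >= 5.0).sum() / d.size)
    if kind.startswith("D"):
        try:
            x = float(kind[1:])
        except ValueError:
            raise ParameterError(f"unknown DVH index {kind!r}") from None
        if not 0 < x < 100:
            raise ParameterError("D_x requires 0 < x < 100")
        curve = dvh(dose, mask, bin_width)
        target = x / 100.0
        f, axis = curve.volume_fraction, curve.dose_axis
        if f[-1] >= target:
            return float(axis[-1])
        idx = int(np.argmax(f < target))          # first bin below the target fraction
        d0, d1, f0, f1 = axis[idx - 1], axis[idx], f[idx - 1], f[idx]
        if f0 == f1:
            return float(d0)
        return float(d0 + (d1 - d0) * (f0 - target) / (f0 - f1))
    raise ParameterError(f"unknown DVH index {kind!r}")


def gamma_3d(ref: DoseGrid, evl: DoseGrid, dose_pct: float = 3.0,
             dta_mm: float = 3.0, threshold_pct: float = 10.0,
             subvoxel_factor: int = 3, search_factor: float = 3.0) -> GammaResult:
    """3-D gamma analysis with global normalization.

    For every reference voxel above ``threshold_pct`` % of the reference
    maximum, gamma is the minimum over evaluated positions r within
    ``search_factor * dta_mm`` of
    ``sqrt((D_eval(r) - D_ref(p))^2 / dD^2 + |r - p|^2 / dta^2)`` with
    ``dD = dose_pct % of max(ref)``; the evaluated dose is trilinearly
    interpolated on a ``subvoxel_factor``-refined offset grid.  Voxels below
    the threshold are excluded (NaN in the map) and do not count toward the
    passing rate (fraction of evaluated voxels with gamma <= 1).
    """
    require_same_grid(ref, evl, "dose grids")
    if dose_pct <= 0 or dta_mm <= 0:
        raise ParameterError("dose_pct and dta_mm must be positive")
    if subvoxel_factor < 1:
        raise ParameterError("subvoxel_factor must be >= 1")
    dmax = float(ref.values.max())
    if dmax <= 0:
        raise ParameterError("reference dose grid is identically zero")
    dd = dose_pct / 100.0 * dmax
    cutoff = threshold_pct / 100.0 * dmax
    evaluated = ref.values >= cutoff
    if not evaluated.any():
        raise ParameterError("low-dose threshold excludes every voxel")

    spacing = np.asarray(evl.spacing, dtype=float)
    radius = search_factor * dta_mm
    steps = [np.arange(-int(np.floor(radius / (s / subvoxel_factor))),
                       int(np.floor(radius / (s / subvoxel_factor))) + 1)
             * (s / subvoxel_factor) for s in spacing]

    gamma_sq = np.full(ref.shape, np.inf)
    base = np.indices(ref.shape, dtype=float)
    for oz in steps[0]:
        for oy in steps[1]:
            for ox in steps[2]:
                dist_sq = oz * oz + oy * oy + ox * ox
                if dist_sq > radius * radius:
                    continue
                spatial = dist_sq / (dta_mm * dta_mm)
                if np.all(spatial >= gamma_sq[evaluated]):
                    continue
                offset_vox = np.array([oz, oy, ox]) / spacing
                if np.allclose(offset_vox, np.round(offset_vox), atol=1e-9):
                    shifted = _integer_shift(evl.values, offset_vox.round().astype(int))
                else:
                    coords = [base[c] + offset_vox[c] for c in range(3)]
                    shifted = ndimage.map_coordinates(
                        evl.values, coords, order=1, mode="constant", cval=np.nan
                    )
                g = (shifted - ref.values) ** 2 / (dd * dd) + spatial
                np.fmin(gamma_sq, g, out=gamma_sq, where=~np.isnan(g))
    gamma_map = np.sqrt(gamma_sq)
    gamma_map[~evaluated] = np.nan
    vals = gamma_map[evaluated]
    return GammaResult(gamma_map, float((vals <= 1.0).mean()),
                       (dose_pct, dta_mm, threshold_pct))


def _integer_shift(values: np.ndarray, shift_vox) -> np.ndarray:
    """values sampled at p + shift (integer voxels), NaN outside the grid."""
    out = np.full(values.shape, np.nan)
    src = []
    dst = []
    for n, s in zip(values.shape, shift_vox):
        lo, hi = max(0, s), min(n, n + s)
        src.append(slice(lo, hi))
        dst.append(slice(lo - s, hi - s))
    if all(sl.start < sl.stop for sl in src):
        out[tuple(dst)] = values[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# statistics


def paired_t_test(a, b) -> tuple[float, float]:
    """Classical paired Student's t-test (two-sided, df = n - 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("inputs must be 1-D sequences of equal length")
    if a.size < 2:
        raise ParameterError("need at least 2 paired observations")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        raise DegenerateInputError("paired differences have zero variance")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
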