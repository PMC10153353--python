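"""Image-quality, structure, dose and statistics metrics.

The 3-D gamma implementation is cross-checked against an exhaustive
brute-force oracle written independently here (per-voxel loop over all
integer offsets inside the search sphere).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctdirnet import (
    DoseGrid,
    StructureSet,
    cdvh,
    cdvh_quantile,
    dsc,
    dvh,
    dvh_index,
    gamma_3d,
    mae_hu,
    paired_t_test,
    structure_report,
)
from ctdirnet.errors import DegenerateInputError, ParameterError

RNG = np.random.default_rng(4)

# computed by the classical hand formula (mean difference over sd/sqrt(n))
# for the vectors below before the implementation existed
TTEST_A = [12.1, 14.3, 11.9, 13.5, 12.8, 14.0, 13.1, 12.5]
TTEST_B = [11.4, 13.9, 12.0, 12.9, 12.1, 13.8, 12.5, 12.2]
TTEST_T = 4.269101219838345
TTEST_P = 0.0037047773275857916


def brute_force_gamma(ref: DoseGrid, evl: DoseGrid, dose_pct, dta_mm, threshold_pct,
                      search_factor=3.0):
    """Independent oracle: exhaustive integer-voxel search per voxel."""
    dmax = ref.values.max()
    dd = dose_pct / 100.0 * dmax
    cutoff = threshold_pct / 100.0 * dmax
    spacing = np.array(ref.spacing)
    radius = search_factor * dta_mm
    ranges = [np.arange(-int(np.floor(radius / s)), int(np.floor(radius / s)) + 1)
              for s in spacing]
    shape = ref.shape
    out = np.full(shape, np.nan)
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if ref.values[z, y, x] < cutoff:
                    continue
                best = np.inf
                for oz in ranges[0]:
                    zz = z + oz
                    if not 0 <= zz < shape[0]:
                        continue
                    for oy in ranges[1]:
                        yy = y + oy
                        if not 0 <= yy < shape[1]:
                            continue
                        for ox in ranges[2]:
                            xx = x + ox
                            if not 0 <= xx < shape[2]:
                                continue
                            dist2 = ((oz * spacing[0]) ** 2 + (oy * spacing[1]) ** 2
                                     + (ox * spacing[2]) ** 2)
                            if dist2 > radius * radius:
                                continue
                            val = ((evl.values[zz, yy, xx] - ref.values[z, y, x]) ** 2
                                   / (dd * dd) + dist2 / (dta_mm * dta_mm))
                            best = min(best, val)
                out[z, y, x] = np.sqrt(best)
    return out


class TestMae:
    def test_identical_volumes_give_zero(self):
        x = RNG.random((5, 5, 5))
        assert mae_hu(x, x) == 0.0

    def test_uniform_offset(self):
        x = RNG.random((5, 5, 5)) * 100
        assert mae_hu(x, x + 25.0) == pytest.approx(25.0)

    def test_two_voxel_toy(self):
        assert mae_hu(np.array([[[0.0]], [[100.0]]]),
                      np.array([[[10.0]], [[80.0]]])) == pytest.approx(15.0)

    def test_empty_mask_raises(self):
        x = RNG.random((4, 4, 4))
        with pytest.raises(ParameterError):
            mae_hu(x, x, mask=np.zeros_like(x, dtype=bool))


class TestCdvh:
    def _curve(self):
        a = np.zeros((1, 2, 2))
        b = np.array([0.0, 10.0, 20.0, 30.0]).reshape(1, 2, 2)
        return cdvh(a, b, np.arange(0.0, 41.0, 1.0))

    def test_identical_volumes_give_zero_everywhere(self):
        x = RNG.random((4, 4, 4))
        curve = cdvh(x, x, np.arange(0.0, 10.0, 1.0))
        assert np.all(curve.exceed_fraction == 0.0)

    def test_strict_exceedance_counting(self):
        curve = self._curve()
        assert curve.exceed_fraction[15] == pytest.approx(0.5)
        assert curve.exceed_fraction[30] == 0.0      # strict ">" at the max

    def test_curve_is_non_increasing(self):
        a, b = RNG.random((6, 6, 6)), RNG.random((6, 6, 6))
        curve = cdvh(a, b, np.linspace(0, 1, 50))
        assert np.all(np.diff(curve.exceed_fraction) <= 0)

    def test_quantile_matches_direct_counting(self):
        assert cdvh_quantile(self._curve(), 0.25) == pytest.approx(20.0)

    def test_quantile_of_identical_volumes_is_zero(self):
        x = RNG.random((4, 4, 4))
        curve = cdvh(x, x, np.arange(0.0, 5.0, 1.0))
        assert cdvh_quantile(curve, 0.05) == 0.0

    def test_quantile_near_one_approaches_smallest_difference(self):
        curve = self._curve()
        assert cdvh_quantile(curve, 0.999) <= 10.0

    def test_unsorted_thresholds_raise(self):
        x = RNG.random((3, 3, 3))
        with pytest.raises(ParameterError):
            cdvh(x, x, np.array([5.0, 1.0]))


class TestDsc:
    def test_identity_is_one(self):
        m = RNG.random((5, 5, 5)) > 0.5
        assert dsc(m, m) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros_like(a)
        a[0], b[1] = True, True
        assert dsc(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((1, 10, 20), dtype=bool)
        b = np.zeros_like(a)
        a[0, :, :10] = True              # |a| = 100
        b[0, :, 5:15] = True             # |b| = 100, overlap 50
        assert dsc(a, b) == pytest.approx(0.5)

    def test_both_empty_returns_one_with_warning(self):
        e = np.zeros((3, 3, 3), dtype=bool)
        with pytest.warns(UserWarning):
            assert dsc(e, e) == 1.0


class TestStructureReport:
    def test_identical_sets_score_perfectly(self):
        m = RNG.random((6, 6, 6)) > 0.6
        s = StructureSet({"a": m, "b": ~m})
        table = structure_report(s, s)
        body = table[table.structure != "average"]
        assert np.allclose(body.ssim, 1.0) and np.allclose(body.dsc, 1.0)

    def test_k_plus_one_rows_and_mean_aggregation(self):
        masks = {f"s{i}": RNG.random((5, 5, 5)) > 0.5 for i in range(3)}
        jittered = {k: np.roll(v, 1, axis=0) for k, v in masks.items()}
        table = structure_report(StructureSet(masks), StructureSet(jittered))
        assert len(table) == 4
        body = table[table.structure != "average"]
        agg = table[table.structure == "average"].iloc[0]
        assert agg.ssim == pytest.approx(body.ssim.mean())
        assert agg.dsc == pytest.approx(body.dsc.mean())


class TestDvh:
    def test_uniform_dose_is_a_step_function(self):
        dose = DoseGrid(np.full((4, 4, 4), 20.0), (2, 2, 2))
        mask = np.ones((4, 4, 4), dtype=bool)
        curve = dvh(dose, mask, bin_width=0.5)
        assert np.all(curve.volume_fraction[curve.dose_axis <= 20.0] == 1.0)
        assert np.all(curve.volume_fraction[curve.dose_axis > 20.0] == 0.0)

    def test_two_level_dose_counts(self):
        vals = np.full((2, 2, 2), 2.0)
        vals[1] = 10.0
        dose = DoseGrid(vals, (1, 1, 1))
        curve = dvh(dose, np.ones_like(vals, dtype=bool), bin_width=1.0)
        assert curve.volume_fraction[curve.dose_axis == 5.0][0] == pytest.approx(0.5)

    def test_curve_non_increasing_and_starts_at_one(self):
        dose = DoseGrid(RNG.random((5, 5, 5)) * 30, (2, 2, 2))
        curve = dvh(dose, np.ones((5, 5, 5), dtype=bool))
        assert curve.volume_fraction[0] == 1.0
        assert np.all(np.diff(curve.volume_fraction) <= 0)


class TestDvhIndex:
    def _uniform(self, value=20.0):
        return DoseGrid(np.full((4, 4, 4), value), (2, 2, 2)), np.ones((4, 4, 4), bool)

    def test_uniform_dose_gives_equal_indices(self):
        dose, mask = self._uniform()
        for kind in ("D95", "D5", "Dmean", "Dmax"):
            assert dvh_index(dose, mask, kind) == pytest.approx(20.0, abs=0.05)
        assert dvh_index(dose, mask, "V5") == pytest.approx(100.0)

    def test_two_level_dose_exact_values(self):
        vals = np.full((2, 2, 2), 2.0)
        vals[1] = 10.0
        dose = DoseGrid(vals, (1, 1, 1))
        mask = np.ones_like(vals, dtype=bool)
        assert dvh_index(dose, mask, "Dmean") == pytest.approx(6.0)
        assert dvh_index(dose, mask, "V5") == pytest.approx(50.0)
        assert dvh_index(dose, mask, "Dmax") == pytest.approx(10.0)

    def test_d95_never_exceeds_d5(self):
        dose = DoseGrid(RNG.random((6, 6, 6)) * 60, (2, 2, 2))
        mask = RNG.random((6, 6, 6)) > 0.3
        assert dvh_index(dose, mask, "D95") <= dvh_index(dose, mask, "D5")

    def test_dx_matches_sorting_quantile_at_dense_sampling(self):
        # both are inversions of the empirical survival function; they agree
        # once the voxel count makes order-statistic gaps small
        for _ in range(3):
            dose = DoseGrid(RNG.random((16, 16, 16)) * 50, (2, 2, 2))
            mask = RNG.random((16, 16, 16)) > 0.4
            for x in (95, 50, 5):
                direct = np.percentile(dose.values[mask], 100 - x)
                assert dvh_index(dose, mask, f"D{x}") == pytest.approx(direct, abs=0.15)

    def test_unknown_index_raises(self):
        dose, mask = self._uniform()
        with pytest.raises(ParameterError):
            dvh_index(dose, mask, "Q50")


class TestGamma:
    def test_identical_grids_pass_everywhere_with_zero_gamma(self):
        vals = RNG.random((10, 10, 10)) * 50 + 1
        ref = DoseGrid(vals, (2.5, 2.5, 2.5))
        res = gamma_3d(ref, DoseGrid(vals.copy(), ref.spacing), 3, 3, 10,
                       subvoxel_factor=1)
        assert res.passing_rate == 1.0
        evaluated = np.isfinite(res.gamma_map)
        assert np.allclose(res.gamma_map[evaluated], 0.0)

    def test_uniform_two_percent_offset_gives_two_thirds(self):
        vals = np.full((8, 8, 8), 50.0)
        ref = DoseGrid(vals, (2.5, 2.5, 2.5))
        evl = DoseGrid(vals * 1.02, ref.spacing)
        res = gamma_3d(ref, evl, 3, 3, 10, subvoxel_factor=1)
        evaluated = np.isfinite(res.gamma_map)
        assert np.allclose(res.gamma_map[evaluated], 2.0 / 3.0, atol=1e-9)
        assert res.passing_rate == 1.0

    def test_matches_brute_force_oracle_on_random_grids(self):
        rng = np.random.default_rng(77)
        for trial in range(8):
            vals = rng.random((16, 16, 16)) * 60
            evl = vals + rng.normal(0, 2.0, vals.shape)
            ref = DoseGrid(vals, (2.5, 2.5, 2.5))
            evg = DoseGrid(np.maximum(evl, 0), ref.spacing)
            res = gamma_3d(ref, evg, 3, 3, 10, subvoxel_factor=1)
            oracle = brute_force_gamma(ref, evg, 3, 3, 10)
            finite = np.isfinite(oracle)
            assert np.array_equal(finite, np.isfinite(res.gamma_map))
            assert np.max(np.abs(res.gamma_map[finite] - oracle[finite])) < 1e-6

    def test_tighter_dose_criterion_never_lowers_gamma(self):
        rng = np.random.default_rng(5)
        vals = rng.random((10, 10, 10)) * 40
        ref = DoseGrid(vals, (2.5, 2.5, 2.5))
        evl = DoseGrid(vals * (1 + rng.normal(0, 0.02, vals.shape)).clip(min=0),
                       ref.spacing)
        loose = gamma_3d(ref, evl, 3, 3, 10, subvoxel_factor=1)
        tight = gamma_3d(ref, evl, 2, 2, 10, subvoxel_factor=1)
        finite = np.isfinite(loose.gamma_map)
        assert np.all(tight.gamma_map[finite] >= loose.gamma_map[finite] - 1e-12)
        assert tight.passing_rate <= loose.passing_rate

    def test_zero_reference_raises(self):
        z = DoseGrid(np.zeros((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ParameterError):
            gamma_3d(z, z, 3, 3, 10)


class TestPairedT:
    def test_symmetric_differences_give_zero_t_and_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a - np.array([1.0, -1.0, 1.0, -1.0])
        t, p = paired_t_test(a, b)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_reference_vectors_match_hand_computation(self):
        t, p = paired_t_test(TTEST_A, TTEST_B)
        assert t == pytest.approx(TTEST_T, abs=1e-10)
        assert p == pytest.approx(TTEST_P, abs=1e-10)

    def test_constant_offset_zero_variance_raises(self):
        a = np.arange(10.0)
        with pytest.raises(DegenerateInputError):
            paired_t_test(a, a + 2.0)

    def test_too_short_input_raises(self):
        with pytest.raises(ParameterError):
            paired_t_test([1.0], [2.0])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_cdvh_monotone_on_random_inputs(seed):
    rng = np.random.default_rng(seed)
    a = rng.random((5, 5, 5)) * 100
    b = rng.random((5, 5, 5)) * 100
    curve = cdvh(a, b, np.linspace(0, 120, 40))
    assert np.all(np.diff(curve.exceed_fraction) <= 0)
    assert np.all((curve.exceed_fraction >= 0) & (curve.exceed_fraction <= 1))
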