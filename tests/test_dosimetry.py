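"""Quality factor, range filters, fluence, D, H and spectral summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fntdose.dosimetry import (
    KEV_PER_UM_TO_GY,
    RangeTable,
    angle_summary,
    compute_dose,
    compute_dose_equivalent,
    compute_fluence,
    evaluate_tracks,
    let_spectrum,
    quality_factor,
    range_filter_image,
    range_filter_phase_space,
    split_by_let,
)
from fntdose.errors import ConfigurationError, DomainError


class TestQualityFactor:
    @pytest.mark.parametrize("let,expected", [
        (5.0, 1.0),            # low-LET plateau
        (10.0, 1.0),           # continuity: 0.32*10 - 2.2 = 1
        (50.0, 0.32 * 50 - 2.2),
        (100.0, 29.8),         # left limit of the published step at 100
        (400.0, 15.0),         # 300 / sqrt(400)
    ])
    def test_piecewise_values(self, let, expected):
        assert quality_factor(let) == pytest.approx(expected, rel=1e-12)

    def test_step_at_100(self):
        # the published piecewise form is discontinuous at 100 keV/um
        assert quality_factor(100.0) == pytest.approx(29.8)
        assert quality_factor(100.0 + 1e-9) == pytest.approx(30.0, abs=1e-6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(let=st.floats(0.01, 5000.0))
    def test_q_at_least_one(self, let):
        assert quality_factor(let) >= 1.0 - 1e-12

    def test_domain_error(self):
        with pytest.raises(DomainError):
            quality_factor(0.0)


class TestRangeFilter:
    def test_image_path_slice_counts(self):
        assert range_filter_image(5)          # identifiable over 5 slices
        assert not range_filter_image(4)

    def test_phase_space_cosine_geometry(self):
        # a proton with 19 um of range at 60 degrees cannot reach 10 um of
        # depth (it would need 10 / cos 60 = 20 um of path)
        table = RangeTable(table_energy_mev=[0.1, 100.0],
                           table_range_um=[19.0, 19.0001])
        assert not range_filter_phase_space(1, 1, 0.2, 60.0, table)
        assert range_filter_phase_space(1, 1, 0.2, 0.0, table)

    def test_default_table_anchor(self):
        # ~1.9 MeV proton (LET near the 25 keV/um threshold) reaches ~10 um
        table = RangeTable()
        assert table.proton_range_um(1.9) == pytest.approx(10.0, rel=1e-6)
        assert np.all(np.diff(table.proton_range_um(np.linspace(1, 100, 50))) > 0)

    def test_missing_table_raises(self):
        with pytest.raises(ConfigurationError):
            range_filter_phase_space(1, 1, 10.0, 0.0, None)


class TestSplitAndFluence:
    def test_boundary_convention(self):
        low, high = split_by_let(np.array([25.0, 25.01, 1.0, 400.0]))
        assert low.tolist() == [True, False, True, False]
        assert (low ^ high).all()

    def test_fluence_arithmetic(self):
        val, unc = compute_fluence(610, 0.0122, 1.0)
        assert val == pytest.approx(5.0e4, rel=1e-3)
        assert unc == pytest.approx(math.sqrt(610) / 0.0122, rel=1e-6)

    def test_zero_tracks(self):
        val, unc = compute_fluence(0, 1.0, 1.0)
        assert (val, unc) == (0.0, 0.0)

    def test_invalid_area(self):
        with pytest.raises(DomainError):
            compute_fluence(10, 0.0, 1.0)


class TestDose:
    def test_unit_conversion_constant(self):
        # independent dimensional analysis: 1 keV/um per g/cm^3 per cm^2 =
        # 1e3 eV * 1e4 /cm / g = 1.602e-19 * 1e3 * 1e4 * 1e3 J/kg
        assert KEV_PER_UM_TO_GY == pytest.approx(1.602e-9, rel=2e-4)

    def test_single_track(self):
        d = compute_dose([10.0], [0.0], rho_g_cm3=1.0, area_cm2=1.0)
        assert d == pytest.approx(1.602e-8, rel=2e-4)

    def test_cosine_path_weighting(self):
        d0 = compute_dose([10.0], [0.0], 1.0, 1.0)
        d60 = compute_dose([10.0], [60.0], 1.0, 1.0)
        assert d60 == pytest.approx(2 * d0, rel=1e-12)

    def test_empty_set(self):
        assert compute_dose([], [], 1.0, 1.0) == 0.0

    def test_scaling_in_area_and_density(self):
        let, th = [3.0, 7.0, 40.0], [10.0, 20.0, 30.0]
        d = compute_dose(let, th, 1.0, 1.0)
        assert compute_dose(let, th, 2.0, 1.0) == pytest.approx(d / 2, rel=1e-12)
        assert compute_dose(let, th, 1.0, 4.0) == pytest.approx(d / 4, rel=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0.5, 400.0), st.floats(0.0, 80.0)),
                    min_size=2, max_size=30))
    def test_additivity_and_order_invariance(self, pairs):
        let = np.array([p[0] for p in pairs])
        th = np.array([p[1] for p in pairs])
        d_all = compute_dose(let, th, 1.0, 1.0)
        d_split = compute_dose(let[::2], th[::2], 1.0, 1.0) \
            + compute_dose(let[1::2], th[1::2], 1.0, 1.0)
        assert d_split == pytest.approx(d_all, rel=1e-9)
        perm = np.argsort(let)
        assert compute_dose(let[perm], th[perm], 1.0, 1.0) \
            == pytest.approx(d_all, rel=1e-12)


class TestDoseEquivalent:
    def test_equals_dose_below_q_threshold(self):
        let = [2.0, 5.0, 9.9]
        th = [0.0, 30.0, 50.0]
        assert compute_dose_equivalent(let, th, 1.0, 1.0) \
            == pytest.approx(compute_dose(let, th, 1.0, 1.0), rel=1e-12)

    def test_high_let_amplification(self):
        d = compute_dose([400.0], [0.0], 1.0, 1.0)
        h = compute_dose_equivalent([400.0], [0.0], 1.0, 1.0)
        assert h == pytest.approx(15.0 * d, rel=1e-12)

    def test_h_at_least_d(self, rng):
        let = np.exp(rng.uniform(np.log(0.5), np.log(500), 200))
        th = rng.uniform(0, 80, 200)
        assert compute_dose_equivalent(let, th, 1.0, 1.0) \
            >= compute_dose(let, th, 1.0, 1.0)

    def test_matches_brute_force_summation(self, rng):
        # independent per-track python-loop oracle, 1e-12 relative
        let = np.exp(rng.uniform(np.log(0.5), np.log(500), 500))
        th = rng.uniform(0, 85, 500)
        terms_d, terms_h = [], []
        for L, t in zip(let, th):
            if L < 10:
                q = 1.0
            elif L <= 100:
                q = 0.32 * L - 2.2
            else:
                q = 300.0 / math.sqrt(L)
            di = KEV_PER_UM_TO_GY * L / math.cos(math.radians(t)) / (1.0 * 1.0)
            terms_d.append(di)
            terms_h.append(di * q)
        assert compute_dose(let, th, 1.0, 1.0) \
            == pytest.approx(math.fsum(terms_d), rel=1e-12)
        assert compute_dose_equivalent(let, th, 1.0, 1.0) \
            == pytest.approx(math.fsum(terms_h), rel=1e-12)


class TestSpectraAndSummaries:
    def test_single_track_cumulative_step(self):
        spec = let_spectrum([7.0])
        assert spec["cumulative_h"].tolist() == [1.0]

    def test_high_let_h_fraction_closed_form(self):
        # 99 tracks at LET 2 (Q=1) and one at LET 200: the single high-LET
        # track carries 200*Q(200) / (99*2 + 200*Q(200)) ~ 95.5% of H
        let = np.array([2.0] * 99 + [200.0])
        spec = let_spectrum(let)
        q200 = 300.0 / math.sqrt(200.0)
        expected = 200 * q200 / (99 * 2 + 200 * q200)
        high_fraction = 1.0 - spec["cumulative_h"][-2]
        assert expected == pytest.approx(0.955, abs=0.001)
        assert high_fraction == pytest.approx(expected, rel=1e-9)

    def test_all_low_let_high_panel_empty(self):
        spec = let_spectrum([1.0, 2.0, 3.0])
        assert spec["density_high"].size == 0
        assert np.all(np.diff(spec["cumulative_h"]) >= 0)
        assert spec["cumulative_h"][-1] == pytest.approx(1.0)

    def test_density_normalisation(self, rng):
        let = rng.uniform(0.5, 24.0, 2000)
        spec = let_spectrum(let)
        assert spec["density_low"].sum() * 1.0 == pytest.approx(1.0, rel=1e-9)

    def test_angle_summary_uniform(self, rng):
        th = rng.uniform(0, 50, 20000)
        s = angle_summary(th)
        assert s["median_deg"] == pytest.approx(25.0, abs=1.0)

    def test_angle_summary_single_value(self):
        s = angle_summary([30.0])
        assert s["median_deg"] == 30.0
        assert s["iqr_deg"] == (30.0, 30.0)
        assert abs(s["mode_deg"] - 30.0) <= 0.5

    def test_angle_summary_empty(self):
        with pytest.raises(DomainError):
            angle_summary([])


class TestEvaluateTracks:
    def test_low_high_components_sum(self, rng):
        let = np.concatenate([rng.uniform(0.5, 20, 300),
                              rng.uniform(30, 300, 5)])
        th = rng.uniform(0, 60, 305)
        res = evaluate_tracks(let, th, area_cm2=0.01, n_bootstrap=50, rng=rng)
        assert res.d_mgy_per_gy["low_let"] + res.d_mgy_per_gy["high_let"] \
            == pytest.approx(res.d_mgy_per_gy["total"], rel=1e-9)
        assert res.h_msv_per_gy["low_let"] + res.h_msv_per_gy["high_let"] \
            == pytest.approx(res.h_msv_per_gy["total"], rel=1e-9)
        assert res.n_low + res.n_high == res.n_tracks
        # water density: H (mSv) numerically >= D (mGy)
        assert res.h_msv_per_gy["total"] >= res.d_mgy_per_gy["total"]

    def test_json_round_trip(self, rng, tmp_path):
        from fntdose.dosimetry import DoseResult

        let = rng.uniform(0.5, 20, 50)
        res = evaluate_tracks(let, np.zeros(50), area_cm2=0.01,
                              n_bootstrap=0, with_spectrum=False)
        path = tmp_path / "result.json"
        res.to_json(path)
        back = DoseResult.from_json(path)
        assert back.fluence_per_cm2_per_gy == pytest.approx(
            res.fluence_per_cm2_per_gy)
        assert back.d_mgy_per_gy["total"] == pytest.approx(
            res.d_mgy_per_gy["total"])
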