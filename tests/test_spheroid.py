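"""Spheroid growth rates, inhibition, dose-effect curves and 3D RBE."""

import numpy as np
import pytest

from radiorbe import spheroid
from radiorbe.errors import InputError, UnattainableEffectError, ValidationError
from radiorbe.spheroid import (
    DoseEffectCurve,
    SpheroidTrack,
    aggregate_condition,
    dose_effect_curve,
    growth_increment_percent,
    growth_inhibition,
    growth_rate_endpoint,
    growth_rate_regression,
    rbe_3d,
    rbe_3d_sweep,
)

GRID = np.arange(0.0, 121.0, 24.0)


def linear_track(slope, baseline=500.0, times=GRID, **kw):
    kw.setdefault("spheroid_id", "s1")
    kw.setdefault("cell_line", "T98G")
    kw.setdefault("modality", "XRT")
    kw.setdefault("dose_gy", 2.0)
    return SpheroidTrack(times_h=times, diameters_um=baseline + slope * times, **kw)


class TestTrackValidation:
    def test_requires_time_zero_baseline(self):
        with pytest.raises(InputError, match="baseline"):
            SpheroidTrack("s", "T98G", "XRT", 2.0, np.array([24.0, 48.0]),
                          np.array([500.0, 510.0]))

    def test_requires_increasing_times(self):
        with pytest.raises(InputError):
            SpheroidTrack("s", "T98G", "XRT", 2.0, np.array([0.0, 48.0, 24.0]),
                          np.array([500.0, 510.0, 505.0]))


class TestGrowthRates:
    def test_endpoint_example(self):
        t = SpheroidTrack("s", "a", "XRT", 2.0, np.array([0.0, 120.0]),
                          np.array([500.0, 560.0]))
        assert growth_rate_endpoint(t) == pytest.approx(0.5)

    def test_constant_diameter_zero_rate(self):
        assert growth_rate_endpoint(linear_track(0.0)) == 0.0

    def test_noiseless_published_slope_recovered(self):
        # steepest published photon slope for the glioblastoma line, 6 Gy
        slope, _, r2 = growth_rate_regression(linear_track(-0.3913))
        assert slope == pytest.approx(-0.3913, abs=1e-12)
        assert r2 == pytest.approx(1.0)
        assert growth_rate_endpoint(linear_track(-0.3913)) == pytest.approx(-0.3913)

    def test_regression_slope_example(self):
        slope, intercept, _ = growth_rate_regression(linear_track(-0.225))
        assert slope == pytest.approx(-0.225, abs=1e-12)
        assert intercept == pytest.approx(500.0, abs=1e-9)

    def test_two_point_track_regression_equals_endpoint(self):
        t = SpheroidTrack("s", "a", "XRT", 2.0, np.array([0.0, 72.0]),
                          np.array([480.0, 517.3]))
        assert growth_rate_regression(t)[0] == growth_rate_endpoint(t)

    def test_noisy_track_matches_normal_equations_oracle(self, rng):
        times = GRID
        diam = 500.0 + 0.8 * times + rng.normal(0, 5, times.size)
        t = SpheroidTrack("s", "a", "XRT", 2.0, times, diam)
        slope, intercept, _ = growth_rate_regression(t)
        # textbook normal equations
        xbar, ybar = times.mean(), diam.mean()
        b = ((times - xbar) @ (diam - ybar)) / ((times - xbar) @ (times - xbar))
        assert slope == pytest.approx(b, rel=1e-12)
        assert intercept == pytest.approx(ybar - b * xbar, rel=1e-12)

    @pytest.mark.parametrize(
        "d0,d1,pct", [(500.0, 650.0, 30.0), (500.0, 500.0, 0.0), (500.0, 450.0, -10.0)]
    )
    def test_increment_percent(self, d0, d1, pct):
        t = SpheroidTrack("s", "a", "XRT", 2.0, np.array([0.0, 120.0]),
                          np.array([d0, d1]))
        assert growth_increment_percent(t) == pytest.approx(pct)


class TestAggregate:
    def test_mean_and_sd_over_spheroids(self):
        tracks = [linear_track(s, spheroid_id=f"s{i}")
                  for i, s in enumerate([-0.2, -0.25, -0.3])]
        summ = aggregate_condition(tracks)
        assert summ.slope_um_per_h == pytest.approx(-0.25)
        assert summ.slope_sd == pytest.approx(np.std([-0.2, -0.25, -0.3], ddof=1))
        assert summ.n_spheroids == 3 and summ.method == "regression"

    def test_endpoint_method_tagged(self):
        summ = aggregate_condition([linear_track(-0.2)], method="endpoint")
        assert summ.method == "endpoint"
        assert summ.slope_um_per_h == pytest.approx(-0.2)

    def test_mixed_conditions_rejected(self):
        with pytest.raises(InputError, match="mix"):
            aggregate_condition([linear_track(-0.2), linear_track(-0.2, dose_gy=4.0)])


class TestGrowthInhibition:
    def test_equal_rates_zero(self):
        assert growth_inhibition(1.25, 1.25) == 0.0

    def test_growth_arrest_is_one(self):
        assert growth_inhibition(0.0, 1.25) == 1.0

    def test_shrinkage_exceeds_one(self):
        assert growth_inhibition(-0.625, 1.25) == pytest.approx(1.5)

    def test_strictly_decreasing_in_irradiated_rate(self):
        rates = np.linspace(-1, 1.2, 30)
        vals = [growth_inhibition(r, 1.25) for r in rates]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_nonpositive_control_rejected(self):
        with pytest.raises(InputError):
            growth_inhibition(0.5, 0.0)


class TestDoseEffectCurve:
    def test_zero_dose_anchor_added(self):
        c = DoseEffectCurve("XRT", [2, 4, 6], [0.3, 0.5, 0.7])
        assert c.doses_gy[0] == 0.0 and c.inhibitions[0] == 0.0

    def test_published_non_monotone_photon_pattern_flagged(self):
        # a 6 Gy slope less negative than the 4 Gy one yields non-monotone
        # inhibition; it must be flagged, not silently repaired
        ctrl = aggregate_condition(
            [linear_track(1.1667, modality="CTRL", dose_gy=0.0,
                          cell_line="Saos-2")])
        summaries = [
            aggregate_condition([linear_track(s, dose_gy=d, cell_line="Saos-2")])
            for d, s in [(2.0, -0.3651), (4.0, -0.7262), (6.0, -0.1095)]
        ]
        curve = dose_effect_curve(summaries, ctrl)
        assert not curve.monotone and not curve.monotonised
        with pytest.raises(ValidationError, match="monotone"):
            curve.dose_at_effect(1.0)
        repaired = curve.monotonise()
        assert repaired.monotone and repaired.monotonised
        assert repaired.inhibitions[0] == 0.0

    def test_monotonise_preserves_monotone_data(self):
        c = DoseEffectCurve("XRT", [2, 4, 6], [0.3, 0.5, 0.7]).monotonise()
        np.testing.assert_allclose(c.inhibitions, [0, 0.3, 0.5, 0.7])

    def test_inverse_interpolation_midpoint(self):
        c = DoseEffectCurve("XRT", [2, 4], [0.2, 0.6])
        dose, extrapolated = c.dose_at_effect(0.4)
        assert dose == pytest.approx(3.0) and not extrapolated

    def test_extrapolation_off_by_default(self):
        c = DoseEffectCurve("XRT", [2, 4], [0.2, 0.6])
        with pytest.raises(UnattainableEffectError):
            c.dose_at_effect(0.9)
        dose, flagged = c.dose_at_effect(0.9, extrapolate=True)
        assert flagged and dose == pytest.approx(5.5)


class TestRBE3D:
    @staticmethod
    def scaled_pair(k, effect_per_gy=0.06, doses=(2.0, 4.0, 6.0)):
        """Reference and a test curve equal to the reference at k-fold dose."""
        ref = DoseEffectCurve("XRT", list(doses),
                              [effect_per_gy * d for d in doses])
        test = DoseEffectCurve("CIRT", list(doses),
                               [effect_per_gy * k * d for d in doses])
        return ref, test

    def test_self_rbe_is_exactly_one(self):
        ref, _ = self.scaled_pair(1.0)
        for level in np.linspace(0.01, ref.max_effect, 10):
            r = rbe_3d(ref, ref, float(level))
            assert r.rbe == 1.0 and not r.extrapolation_flag

    @pytest.mark.parametrize("k", [1.0, 2.0, 3.8])
    def test_dose_scaling_recovered(self, k):
        ref, test = self.scaled_pair(k)
        top = min(ref.max_effect, test.max_effect)
        for level in np.linspace(0.01, top, 25):
            r = rbe_3d(ref, test, float(level))
            assert r.rbe == pytest.approx(k, rel=0.02)

    def test_smooth_curves_recovered_within_two_percent_of_dense_oracle(self):
        """Mildly curved saturating inhibition curves related by dose scale
        3.8, sampled only at 0/2/4/6 Gy, still give the scale factor to
        within 2% of the dense-grid inverse of the generating functions."""
        k, lam = 3.8, 0.005
        f = lambda d: 1.0 - np.exp(-lam * np.asarray(d))
        doses = np.array([2.0, 4.0, 6.0])
        ref = DoseEffectCurve("XRT", doses, f(doses))
        test = DoseEffectCurve("CIRT", doses, f(k * doses))
        top = min(ref.max_effect, test.max_effect)
        for level in np.linspace(0.3 * top, 0.95 * top, 12):
            r = rbe_3d(ref, test, float(level))
            dense_ref = -np.log(1 - level) / lam
            dense_test = dense_ref / k
            oracle = dense_ref / dense_test
            assert r.rbe == pytest.approx(oracle, rel=0.02)

    def test_sweep_constant_for_scaled_curves(self):
        ref, test = self.scaled_pair(2.0)
        sweep = rbe_3d_sweep(ref, test, n_levels=15)
        assert np.allclose(sweep.rbe, 2.0, rtol=1e-9)
        assert len(sweep) == 15


class TestAnalyzeSpheroids:
    def test_end_to_end_tables(self):
        from radiorbe import synthetic

        sc = synthetic.preset_spheroid_scenario("T98G", seed=5)
        table = synthetic.gen_spheroid_tracks(sc)
        summaries, dose_effect, rbe = spheroid.analyze_spheroids(table)
        assert set(summaries.modality) == {"CTRL", "XRT", "PRT", "CIRT"}
        assert (summaries.n_spheroids == 16).all()
        # control growth near the preset slope
        ctrl = summaries[summaries.modality == "CTRL"].iloc[0]
        assert ctrl.slope_um_per_h == pytest.approx(sc.control_slope, abs=0.05)
        assert len(rbe) > 0
        assert (rbe.reference_modality == "XRT").all()

    def test_missing_columns_rejected(self):
        import pandas as pd

        with pytest.raises(ValidationError, match="missing columns"):
            spheroid.tracks_from_table(pd.DataFrame({"spheroid_id": []}))
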