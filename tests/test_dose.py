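import math

import numpy as np
import pandas as pd
import pytest

import gradientchip as gc
from gradientchip.cytometry import GradientProfile
from gradientchip.errors import DegenerateDesignError, ExtrapolationError, InsufficientDataError


@pytest.fixture()
def ideal_profile():
    """Ideal steady linear profile over a 1650 um span: 100% -> 0%."""
    pos = np.linspace(5.0, 1645.0, 165)
    pct = 100.0 * (1.0 - (pos - pos[0]) / (pos[-1] - pos[0]))
    return GradientProfile(pos, pct)


class TestConcentrationAt:
    def test_source_face_full_concentration(self, ideal_profile):
        assert gc.concentration_at(5.0, ideal_profile, 5.0) == pytest.approx(5.0)

    def test_midpoint_half_concentration(self, ideal_profile):
        assert gc.concentration_at(825.0, ideal_profile, 5.0) == pytest.approx(2.5, rel=1e-3)

    def test_sink_face_zero(self, ideal_profile):
        assert gc.concentration_at(1645.0, ideal_profile, 5.0) == pytest.approx(0.0, abs=1e-9)

    def test_outside_span_raises(self, ideal_profile):
        with pytest.raises(ExtrapolationError):
            gc.concentration_at(-50.0, ideal_profile, 5.0)
        with pytest.raises(ExtrapolationError):
            gc.concentration_at(1700.0, ideal_profile, 5.0)


def _static_track(x_um, times):
    return pd.DataFrame(
        {"track_id": 1, "time_min": times, "x_um": x_um, "y_um": 100.0}
    )


def _profiles_from_values(times, values, c0=5.0):
    """Spatially flat profile per time point whose value is values[t]."""
    pos = np.linspace(0.0, 1650.0, 50)
    return {
        float(t): GradientProfile(pos, np.full(50, v / c0 * 100.0))
        for t, v in zip(times, values)
    }


class TestMeanExposure:
    TIMES = [0.0, 5.0, 30.0, 45.0, 60.0]

    def test_constant_concentration(self):
        profiles = _profiles_from_values(self.TIMES, [2.0] * 5)
        rec = gc.mean_exposure(_static_track(800.0, self.TIMES), profiles, 5.0, 0.0, 60.0)
        assert rec.mean_concentration_ug_ml == pytest.approx(2.0)

    def test_hand_trapezoid(self):
        # (2.5 + 37.5 + 30 + 30) / 60 = 1.667
        profiles = _profiles_from_values(self.TIMES, [0.0, 1.0, 2.0, 2.0, 2.0])
        rec = gc.mean_exposure(_static_track(800.0, self.TIMES), profiles, 5.0, 0.0, 60.0)
        assert rec.mean_concentration_ug_ml == pytest.approx(100.0 / 60.0, rel=1e-6)

    def test_five_point_trapezoid_close_to_dense_quadrature(self):
        c_of_t = lambda t: 2.5 * (1.0 - math.exp(-t / 20.0))
        profiles = _profiles_from_values(self.TIMES, [c_of_t(t) for t in self.TIMES])
        rec = gc.mean_exposure(_static_track(800.0, self.TIMES), profiles, 5.0, 0.0, 60.0)
        dense_t = np.linspace(0.0, 60.0, 61)
        dense = np.trapezoid([c_of_t(t) for t in dense_t], dense_t) / 60.0
        assert rec.mean_concentration_ug_ml == pytest.approx(dense, rel=0.10)

    def test_single_time_point_insufficient(self):
        profiles = _profiles_from_values([0.0], [2.0])
        with pytest.raises(InsufficientDataError):
            gc.mean_exposure(_static_track(800.0, [0.0]), profiles, 5.0, 0.0, 60.0)


class TestMorphologyDelta:
    def test_area_shrink_positive(self):
        r0 = pd.Series({"area_px": 1000, "eccentricity": 0.8, "track_id": 1, "time_min": 0.0})
        r1 = pd.Series({"area_px": 800, "eccentricity": 0.8, "track_id": 1, "time_min": 60.0})
        d = gc.morphology_delta(r0, r1)
        assert d.delta_area == pytest.approx(0.20)

    def test_rounding_positive(self):
        r0 = pd.Series({"area_px": 1000, "eccentricity": 0.8, "track_id": 1, "time_min": 0.0})
        r1 = pd.Series({"area_px": 1000, "eccentricity": 0.5, "track_id": 1, "time_min": 60.0})
        d = gc.morphology_delta(r0, r1)
        assert d.delta_eccentricity == pytest.approx(0.3)

    def test_unchanged_cell_zero_deltas(self):
        r = pd.Series({"area_px": 500, "eccentricity": 0.6, "track_id": 2, "time_min": 30.0})
        d = gc.morphology_delta(r, r)
        assert d.delta_area == 0.0 and d.delta_eccentricity == 0.0

    def test_fractional_eccentricity_mode(self):
        r0 = pd.Series({"area_px": 1000, "eccentricity": 0.8, "track_id": 1, "time_min": 0.0})
        r1 = pd.Series({"area_px": 1000, "eccentricity": 0.6, "track_id": 1, "time_min": 60.0})
        d = gc.morphology_delta(r0, r1, eccentricity_mode="fractional")
        assert d.delta_eccentricity == pytest.approx(0.25)


def _pool(concs, deltas, time=60.0):
    return pd.DataFrame(
        {
            "track_id": np.arange(len(concs)),
            "time_min": time,
            "mean_concentration_ug_ml": concs,
            "delta_area": deltas,
        }
    )


class TestPoolAndBin:
    def test_single_cell_per_bin(self):
        pooled = _pool([0.5, 1.5, 2.5, 3.5, 4.5], [0.1, 0.2, 0.3, 0.4, 0.5])
        out = gc.pool_and_bin(pooled, np.linspace(0, 5, 6), [60.0], n_min=1)
        assert (out["median"] == [0.1, 0.2, 0.3, 0.4, 0.5]).all()
        assert (out["q3"] - out["q1"] == 0.0).all()

    def test_counts_conserved_across_bins(self):
        rng = np.random.default_rng(0)
        pooled = _pool(rng.uniform(0, 5, 500), rng.normal(0, 0.1, 500))
        out = gc.pool_and_bin(pooled, np.linspace(0, 5, 6), [60.0])
        assert out["n"].sum() == 500

    def test_single_chamber_pooling_identity(self):
        rng = np.random.default_rng(1)
        chamber = _pool(rng.uniform(0, 5, 100), rng.normal(0.1, 0.05, 100))
        edges = np.linspace(0, 5, 6)
        alone = gc.pool_and_bin(chamber, edges, [60.0])
        merged = gc.pool_and_bin(pd.concat([chamber]), edges, [60.0])
        pd.testing.assert_frame_equal(alone, merged)

    def test_top_bin_exceeds_bottom_for_responding_cells(self):
        rng = np.random.default_rng(2)
        concs = rng.uniform(0, 5, 400)
        h = concs**2 / (concs**2 + 1.0)
        deltas = 0.4 * h + rng.normal(0, 0.01, 400)
        out = gc.pool_and_bin(_pool(concs, deltas), np.linspace(0, 5, 6), [60.0])
        assert out.iloc[-1]["median"] > out.iloc[0]["median"]

    def test_empty_pool_rejected(self):
        with pytest.raises(InsufficientDataError):
            gc.pool_and_bin(_pool([], []), np.linspace(0, 5, 6), [60.0])


class TestHillThresholdFit:
    def _synthetic(self, rng, n=500, emax=0.4, ec50=1.0, hill_n=2.0, noise=0.0):
        conc = rng.uniform(0.0, 5.0, n)
        h = conc**hill_n / (conc**hill_n + ec50**hill_n)
        return conc, emax * h + (rng.normal(0, noise, n) if noise else 0.0)

    def test_noiseless_recovery_within_ten_percent(self):
        conc, delta = self._synthetic(np.random.default_rng(0))
        fit = gc.fit_threshold(conc, delta, n_bootstrap=0)
        assert fit.ec50_ug_ml == pytest.approx(1.0, rel=0.10)
        assert fit.emax_eff == pytest.approx(0.4, rel=0.05)

    def test_all_zero_response_flagged_not_crashed(self):
        rng = np.random.default_rng(1)
        fit = gc.fit_threshold(rng.uniform(0, 5, 100), np.zeros(100), n_bootstrap=0)
        assert "degenerate-response" in fit.flags
        assert fit.emax_eff == 0.0

    def test_null_effect_ci_contains_zero(self):
        rng = np.random.default_rng(2)
        conc = rng.uniform(0, 5, 200)
        delta = rng.normal(0.0, 0.05, 200)  # emax = 0 truth
        fit = gc.fit_threshold(conc, delta, n_bootstrap=100, seed=5)
        assert fit.ci_emax[0] <= 0.0 <= fit.ci_emax[1]

    def test_too_few_cells_rejected(self):
        with pytest.raises(DegenerateDesignError):
            gc.fit_threshold(np.linspace(0, 5, 10), np.zeros(10))

    def test_no_concentration_spread_rejected(self):
        with pytest.raises(DegenerateDesignError):
            gc.fit_threshold(np.full(50, 2.0), np.random.default_rng(0).normal(0, 0.1, 50))

    def test_results_summary_and_predict(self):
        conc, delta = self._synthetic(np.random.default_rng(3), noise=0.02)
        model = gc.HillThresholdModel(conc, delta)
        res = model.fit(n_bootstrap=50, seed=1)
        text = res.summary()
        assert "EC50" in text and "emax_eff" in text
        pred = res.predict([0.0, 1.0, 100.0])
        assert pred[0] == pytest.approx(0.0, abs=1e-9)
        assert pred[2] == pytest.approx(res.params["emax_eff"], rel=0.05)

    def test_trend_statistic_detects_monotone_response(self):
        rng = np.random.default_rng(4)
        conc, delta = self._synthetic(rng, noise=0.02)
        pooled = _pool(conc, delta)
        trend = gc.monotonic_trend(pooled, "delta_area")
        assert trend.iloc[0]["kendall_tau"] > 0.3
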