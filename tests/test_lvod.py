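"""Filter battery (boundary strictness), decomposition fit, annual indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from amazonagc import (FitConfig, annual_indices, apply_quality_masks,
                       filter_rfi, fit_seasonal_trend, reconcile_orbits,
                       remove_outliers, run_lvod_pipeline)
from amazonagc.calibration import vod_to_agc

from conftest import make_obs


def _row(cell=0, date="2015-02-01", orbit="ASC", vod=0.5, tb=3.0, flag=0):
    return (cell, date, orbit, vod, tb, flag)


class TestQualityMasks:
    def test_inundated_cell_above_quarter_removed(self):
        obs = make_obs([_row(cell=0), _row(cell=1)])
        out = apply_quality_masks(obs, {0: 0.30, 1: 0.0})
        assert set(out["cell_id"]) == {1}

    def test_exactly_25_percent_retained(self):
        obs = make_obs([_row(cell=0)])
        out = apply_quality_masks(obs, {0: 0.25})
        assert len(out) == 1

    def test_clean_observation_passes_unchanged(self):
        obs = make_obs([_row()])
        out = apply_quality_masks(obs, {0: 0.0})
        pd.testing.assert_frame_equal(out, obs)

    def test_flagged_observation_removed(self):
        obs = make_obs([_row(flag=4), _row()])
        assert len(apply_quality_masks(obs, {0: 0.0})) == 1

    def test_unknown_cell_raises(self):
        obs = make_obs([_row(cell=7)])
        with pytest.raises(KeyError):
            apply_quality_masks(obs, {0: 0.0})


class TestRfiFilter:
    @pytest.mark.parametrize("tb,kept", [(9.0, False), (8.0, True), (7.9, True)])
    def test_threshold_is_strict(self, tb, kept):
        out = filter_rfi(make_obs([_row(tb=tb)]))
        assert len(out) == (1 if kept else 0)

    def test_clean_stream_identity(self):
        obs = make_obs([_row(tb=t) for t in (1, 3, 5, 8)])
        pd.testing.assert_frame_equal(filter_rfi(obs), obs)

    def test_negative_tb_rmse_rejected(self):
        with pytest.raises(ValueError):
            filter_rfi(make_obs([_row(tb=-1.0)]))


class TestOrbitReconciliation:
    def _split_obs(self, asc_vod, desc_vod, desc_tb=6.0):
        rows = [_row(date=f"2015-01-{d:02d}", orbit="ASC", vod=asc_vod, tb=3.0)
                for d in range(1, 11)]
        rows += [_row(date=f"2015-02-{d:02d}", orbit="DESC", vod=desc_vod,
                      tb=desc_tb) for d in range(1, 11)]
        return make_obs(rows)

    def test_offending_trimester_drops_high_tb(self):
        out = reconcile_orbits(self._split_obs(0.80, 0.86, desc_tb=6.0))
        assert not (out["orbit"] == "DESC").any()  # all DESC had tb 6 > 5
        assert (out["orbit"] == "ASC").sum() == 10

    def test_difference_of_exactly_005_is_retained(self):
        out = reconcile_orbits(self._split_obs(0.80, 0.85, desc_tb=6.0))
        assert len(out) == 20

    def test_same_day_pair_keeps_lower_tb(self):
        obs = make_obs([_row(orbit="ASC", tb=3.0, vod=0.5),
                        _row(orbit="DESC", tb=4.0, vod=0.6)])
        out = reconcile_orbits(obs)
        assert len(out) == 1 and out.iloc[0]["orbit"] == "ASC"

    def test_farther_mode_drops_only_the_deviant_orbit(self):
        """Alternative reconciliation: only the orbit farther from the
        pooled trimester mean loses its high-TB-RMSE observations."""
        # 10 ASC at 0.80 (tb 6) vs 2 DESC at 0.92 (tb 6): DESC is farther
        rows = [(0, f"2015-01-{d:02d}", "ASC", 0.80, 6.0, 0)
                for d in range(1, 11)]
        rows += [(0, f"2015-02-{d:02d}", "DESC", 0.92, 6.0, 0) for d in (1, 2)]
        out = reconcile_orbits(make_obs(rows), mode="farther")
        assert (out["orbit"] == "ASC").sum() == 10
        assert not (out["orbit"] == "DESC").any()

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="reconciliation mode"):
            reconcile_orbits(make_obs([_row()]), mode="nope")

    def test_single_orbit_trimester_skips_difference_test(self):
        obs = make_obs([_row(date=f"2015-01-{d:02d}", tb=6.0) for d in (1, 3, 5)])
        out = reconcile_orbits(obs)
        assert len(out) == 3


class TestOutlierFilter:
    def test_hand_oracle_two_sd(self):
        """{0.8 x9, 1.6}: mean .88, sd(ddof=1) .2530 -> 1.6 is removed."""
        vals = [0.8] * 9 + [1.6]
        obs = make_obs([_row(date=f"2015-01-{d+1:02d}", vod=v)
                        for d, v in enumerate(vals)])
        mean, sd = np.mean(vals), np.std(vals, ddof=1)
        assert abs(1.6 - mean) > 2 * sd and abs(0.8 - mean) <= 2 * sd
        out = remove_outliers(obs)
        assert len(out) == 9 and (out["vod"] == 0.8).all()

    def test_constant_series_untouched(self):
        obs = make_obs([_row(date=f"2015-01-{d:02d}") for d in range(1, 8)])
        assert len(remove_outliers(obs)) == 7

    def test_two_observations_pass_through(self):
        obs = make_obs([_row(vod=0.1), _row(date="2015-02-02", vod=5.0)])
        assert len(remove_outliers(obs)) == 2


class TestFilterProperties:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 28), st.floats(0.1, 1.2),
                              st.floats(0, 12)), min_size=1, max_size=40))
    def test_filters_idempotent_and_monotone(self, triples):
        """RFI and orbit filters are idempotent; every filter only removes.

        The outlier filter is deliberately single-pass (mean and SD are
        computed once on the incoming set, never re-estimated), so for it
        only monotone data loss is guaranteed.
        """
        obs = make_obs([_row(date=f"2015-03-{d:02d}", vod=v, tb=tb)
                        for d, v, tb in triples])
        for f in (filter_rfi, reconcile_orbits):
            once = f(obs)
            assert len(once) <= len(obs)
            pd.testing.assert_frame_equal(f(once), once)
        assert len(remove_outliers(obs)) <= len(obs)

    def test_clean_stream_full_retention(self, static_obs, static_scene):
        """No flags / RFI / offset / outliers -> 100% retention."""
        scene, _ = static_scene
        inund = pd.Series(0.0, index=scene.grid.cell_ids().ravel())
        _, log = run_lvod_pipeline(static_obs, inund, years=list(scene.years))
        assert (log["n_removed"] == 0).all()


class TestSeasonalTrendFit:
    def _obs_from_signal(self, days, values, cell=0):
        dates = pd.Timestamp("2012-01-01") + pd.to_timedelta(days, unit="D")
        return pd.DataFrame({"cell_id": cell, "date": dates, "vod": values,
                             "tb_rmse": 3.0, "orbit": "ASC", "flag": 0})

    def test_constant_input_recovered_exactly(self):
        days = np.arange(0, 900, 3)
        s = fit_seasonal_trend(self._obs_from_signal(days, np.full(len(days), 0.7)))
        np.testing.assert_allclose(s.smoothed, 0.7, atol=1e-9)
        np.testing.assert_allclose(s.trend, 0.7, atol=1e-9)

    def test_pure_sinusoid_leaves_flat_trend(self):
        days = np.arange(0, 365.25 * 3, 2)
        amp = 0.1
        y = 0.6 + amp * np.sin(2 * np.pi * days / 365.25)
        s = fit_seasonal_trend(self._obs_from_signal(days, y))
        assert np.ptp(s.trend) < 0.02 * amp * 2

    def test_trend_recovers_ramp_slope(self):
        days = np.arange(0, 365.25 * 3, 2)
        slope = 0.05  # VOD per year
        y = 0.5 + slope * days / 365.25 + 0.08 * np.sin(2 * np.pi * days / 365.25)
        s = fit_seasonal_trend(self._obs_from_signal(days, y))
        t = (s.dates - s.dates[0]).days / 365.25
        fitted = np.polyfit(t, s.trend, 1)[0]
        assert fitted == pytest.approx(slope, rel=0.05)

    def test_trend_suppresses_annual_harmonic(self):
        days = np.arange(0, 365.25 * 3, 2)
        y = 0.6 + 0.1 * np.sin(2 * np.pi * days / 365.25)
        s = fit_seasonal_trend(self._obs_from_signal(days, y))
        t = (s.dates - s.dates[0]).days / 365.25

        def annual_amp(x):
            c = np.cos(2 * np.pi * t)
            sn = np.sin(2 * np.pi * t)
            return np.hypot(np.mean(x * c) * 2, np.mean(x * sn) * 2)

        assert annual_amp(s.trend) < 0.05 * annual_amp(s.smoothed)

    def test_too_few_dates_raises(self):
        days = np.arange(0, 7)
        with pytest.raises(ValueError, match="8 distinct"):
            fit_seasonal_trend(self._obs_from_signal(days, np.full(7, 0.5)))


class TestAnnualIndices:
    def _series(self, fn):
        days = np.arange(0, 365.25 * 3, 2)
        dates = pd.Timestamp("2012-01-01") + pd.to_timedelta(days, unit="D")
        obs = pd.DataFrame({"cell_id": 0, "date": dates, "vod": fn(days),
                            "tb_rmse": 3.0, "orbit": "ASC", "flag": 0})
        return fit_seasonal_trend(obs)

    def test_constant_series_gives_equal_indices(self):
        s = self._series(lambda d: np.full(len(d), 0.9))
        idx = annual_indices(s, 2013)
        assert idx.max_smooth == pytest.approx(0.9, abs=1e-9)
        assert idx.mean_smooth == pytest.approx(0.9, abs=1e-9)
        assert idx.mean_trend == pytest.approx(0.9, abs=1e-9)

    def test_max_at_least_mean(self):
        s = self._series(lambda d: 0.8 + 0.1 * np.sin(2 * np.pi * d / 365.25))
        idx = annual_indices(s, 2013)
        assert idx.max_smooth > idx.mean_smooth

    def test_window_not_covered_raises(self):
        s = self._series(lambda d: np.full(len(d), 0.5))
        with pytest.raises(ValueError, match="does not cover"):
            annual_indices(s, 2030)

    def test_sparse_window_is_missing_not_zero(self):
        s = self._series(lambda d: np.full(len(d), 0.5))
        assert annual_indices(s, 2013, n_obs_used=5) is None


class TestClosedLoopIndices:
    @staticmethod
    def _stable_cells(truth):
        """Cells without appreciable land-cover change (AGC range < 2%)."""
        agc = truth.agc_density.pivot(index="cell_id", columns="year",
                                      values="agc_mgc_ha")
        rng = (agc.max(axis=1) - agc.min(axis=1)) / agc.mean(axis=1)
        return set(agc.index[rng < 0.02])

    def test_noise_free_mean_trend_tracks_truth_agc(self, clean_obs, clean_scene,
                                                    clean_config):
        """Zero-noise retrieval: trend index maps back to true Jan-Apr AGC
        in cells without land-cover change."""
        scene, truth = clean_scene
        stable = self._stable_cells(truth)
        assert len(stable) >= 4
        inund = pd.Series(0.0, index=scene.grid.cell_ids().ravel())
        idx, _ = run_lvod_pipeline(clean_obs, inund, years=list(scene.years))
        curve = clean_config.calibration_curve
        tr = truth.agc_density.set_index(["cell_id", "year"])["agc_mgc_ha"]
        sub = idx[idx.year.isin(list(scene.years)[1:-1])
                  & idx.cell_id.isin(stable)]
        for _, r in sub.iterrows():
            retrieved = vod_to_agc(curve, r["mean_trend"])
            assert retrieved == pytest.approx(tr.loc[(r.cell_id, r.year)], rel=0.02)

    def test_indices_agree_without_seasonality(self, clean_obs, clean_scene):
        scene, truth = clean_scene
        stable = self._stable_cells(truth)
        inund = pd.Series(0.0, index=scene.grid.cell_ids().ravel())
        idx, _ = run_lvod_pipeline(clean_obs, inund, years=list(scene.years))
        idx = idx[idx.cell_id.isin(stable)]
        rel = (idx["max_smooth"] - idx["mean_trend"]).abs() / idx["mean_trend"]
        assert (rel < 0.02).all()
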