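"""Response model, residual legacy series, duration search, gating."""

import numpy as np
import pandas as pd
import pytest

import fluxlegacy as fl
from fluxlegacy.legacy import weekly_average, wilcoxon_pvalue
from fluxlegacy.preprocessing import N_DOY

from conftest import N_TREES


def _synthetic_anoms(rng, n_years=8, signal="smooth", noise_sd=0.0):
    """Minimal AnomalySeries with a known GPP-anomaly signal."""
    idx = pd.date_range("2000-01-01", periods=365 * n_years, freq="D")
    n = len(idx)
    data = pd.DataFrame(index=idx)
    data["doy"] = idx.dayofyear
    data["in_season"] = (idx.dayofyear > 100) & (idx.dayofyear < 280)
    seg = (idx.year - 2000).to_numpy()
    data["season_id"] = np.where(data["in_season"], seg, -1)
    data["sw_in_anom"] = rng.normal(0, 50, n)
    data["ta_anom"] = rng.normal(0, 2, n)
    data["vpd_anom"] = rng.normal(0, 1, n)
    data["wai_anom"] = rng.normal(0, 10, n)
    if signal == "smooth":
        y = np.tanh(data["sw_in_anom"] / 60) * 3
    else:
        y = np.zeros(n)
    y = y + rng.normal(0, noise_sd, n)
    data["gpp_anom"] = np.where(data["in_season"], y, np.nan)
    data["gpp_gapfilled_anom"] = data["gpp_anom"]
    data.loc[~data["in_season"], data.columns.difference(["doy", "in_season", "season_id"])] = np.nan
    return fl.AnomalySeries(
        data=data, cycles={}, slopes={}, gs_mask=None,
        gs_mean_total_gpp=1000.0, site_id="mini",
    )


class TestResponseModel:
    def test_deterministic_given_seed(self, rng):
        anoms = _synthetic_anoms(rng, noise_sd=0.5)
        m1 = fl.train_response_model(anoms, seed=9, n_trees=50)
        m2 = fl.train_response_model(anoms, seed=9, n_trees=50)
        frame = anoms.data[anoms.data["in_season"]]
        pd.testing.assert_series_equal(m1.predict(frame), m2.predict(frame))

    def test_smooth_signal_high_oob(self, rng):
        anoms = _synthetic_anoms(rng, signal="smooth", noise_sd=0.0)
        m = fl.train_response_model(anoms, n_trees=N_TREES)
        assert m.oob_score > 0.9

    def test_white_noise_oob_near_zero(self, rng):
        anoms = _synthetic_anoms(rng, signal="none", noise_sd=1.0)
        m = fl.train_response_model(anoms, n_trees=N_TREES)
        assert abs(m.oob_score) < 0.1

    def test_too_few_training_days_fatal(self, rng):
        anoms = _synthetic_anoms(rng, n_years=8, noise_sd=0.5)
        inseason = anoms.data.index[anoms.data["in_season"]]
        with pytest.raises(ValueError, match="too few"):
            fl.train_response_model(anoms, exclude=inseason[:-100])

    def test_excluded_days_not_trained_on(self, rng):
        anoms = _synthetic_anoms(rng, noise_sd=0.5)
        inseason = anoms.data.index[anoms.data["in_season"]]
        exclude = inseason[inseason.year == 2003]
        m = fl.train_response_model(anoms, exclude=exclude, n_trees=50)
        total = anoms.data[anoms.data["in_season"]]["gpp_anom"].notna().sum()
        assert m.n_training_days == total - len(exclude)


class TestLegacySeries:
    def test_perfect_model_gives_zero(self, rng):
        anoms = _synthetic_anoms(rng, signal="smooth", noise_sd=0.0)
        window = anoms.data.index[anoms.data["season_id"] == 7]
        m = fl.train_response_model(anoms, exclude=window, n_trees=N_TREES)
        weekly = fl.legacy_series(m, anoms, window)
        assert np.nanmax(np.abs(weekly)) < 0.25

    def test_imposed_offset_recovered(self, rng):
        anoms = _synthetic_anoms(rng, signal="smooth", noise_sd=0.0)
        window = anoms.data.index[anoms.data["season_id"] == 7]
        anoms.data.loc[window, "gpp_gapfilled_anom"] -= 1.0
        m = fl.train_response_model(anoms, exclude=window, n_trees=N_TREES)
        weekly = fl.legacy_series(m, anoms, window)
        assert np.nanmean(weekly) == pytest.approx(-1.0, abs=0.25)

    def test_weekly_block_arithmetic(self):
        vals = pd.Series(np.arange(10.0),
                         index=pd.date_range("2000-01-01", periods=10))
        weekly = weekly_average(vals)
        assert len(weekly) == 2
        assert weekly[0] == pytest.approx(np.mean(np.arange(7)))
        assert weekly[1] == pytest.approx(np.mean(np.arange(7, 10)))

    def test_all_missing_week_dropped(self):
        vals = pd.Series(np.r_[np.full(7, np.nan), np.ones(7)],
                         index=pd.date_range("2000-01-01", periods=14))
        assert len(weekly_average(vals)) == 1


class TestGate:
    def _unc(self, lo=-1.0, hi=1.0):
        return fl.UncertaintyDistribution(
            q05=np.full(N_DOY, lo), q95=np.full(N_DOY, hi), n_iterations=5)

    def test_inside_band_is_zero(self):
        idx = pd.date_range("2000-06-01", periods=3)
        obs = pd.Series([0.5, -0.5, 0.0], index=idx)
        pred = pd.Series(0.0, index=idx)
        assert (fl.gate_legacy(obs, pred, self._unc()) == 0).all()

    def test_exceedance_arithmetic(self):
        idx = pd.date_range("2000-06-01", periods=2)
        obs = pd.Series([-2.0, 3.0], index=idx)
        pred = pd.Series(0.0, index=idx)
        out = fl.gate_legacy(obs, pred, self._unc())
        assert out.iloc[0] == pytest.approx(-1.0)   # d = −2, q05 = −1
        assert out.iloc[1] == pytest.approx(2.0)    # d = 3, q95 = 1

    def test_continuous_and_monotone(self):
        idx = pd.date_range("2000-06-01", periods=1)
        pred = pd.Series(0.0, index=idx)
        grid = np.linspace(-4, 4, 401)
        out = np.array([
            fl.gate_legacy(pd.Series([d], index=idx), pred, self._unc()).iloc[0]
            for d in grid
        ])
        assert (np.diff(out) >= -1e-12).all()
        assert np.max(np.abs(np.diff(out))) < 0.03  # no jumps on a 0.02 grid

    def test_cumulative_normalization(self):
        idx = pd.date_range("2000-06-01", periods=100)
        gated = pd.Series(-0.5, index=idx)
        cum, pct = fl.cumulative_legacy(gated, 1000.0)
        assert cum == pytest.approx(-50.0)
        assert pct == pytest.approx(-5.0)


class TestWilcoxon:
    def test_obvious_shift_significant(self, rng):
        assert wilcoxon_pvalue(rng.normal(-2, 0.5, 15)) < 0.01

    def test_symmetric_noise_not_significant(self, rng):
        p = [wilcoxon_pvalue(rng.normal(0, 1, 15)) for _ in range(50)]
        assert np.mean(np.array(p) < 0.05) < 0.2

    def test_zeros_dropped(self):
        assert wilcoxon_pvalue(np.zeros(10)) == 1.0


class TestDurationSearch:
    def test_censoring_when_legacy_reaches_record_end(self):
        cfg = fl.SyntheticConfig(
            seed=13, years=9,
            droughts=[fl.DroughtSpec(year_index=6, start_doy=150)],
            legacy=fl.LegacySpec(magnitude=-0.25, duration_seasons=3),
        )
        site, truth = fl.generate_site(cfg)
        rc = fl.RunConfig(n_trees=N_TREES, seed=13)
        res = fl.process_site(site, rc)
        assert res.error is None
        lr = res.legacy_results[0]
        assert not lr.converged
        assert lr.normalized_gated_pct < 0  # magnitude retained when censored

    def test_positive_legacy_recovered_with_sign(self):
        cfg = fl.SyntheticConfig(
            seed=21,
            droughts=[fl.DroughtSpec(start_doy=150)],
            legacy=fl.LegacySpec(magnitude=0.15, duration_seasons=1),
        )
        site, truth = fl.generate_site(cfg)
        res = fl.process_site(site, fl.RunConfig(n_trees=N_TREES, seed=21))
        lr = res.legacy_results[0]
        assert lr.sign == "positive"
        assert lr.duration >= 1
        assert lr.normalized_gated_pct > 0

    def test_window_exclusion_barely_moves_other_predictions(self, rng):
        # dropping one season from training shifts predictions elsewhere by
        # far less than the model's own residual spread
        anoms = _synthetic_anoms(rng, signal="smooth", noise_sd=0.5)
        window = anoms.data.index[anoms.data["season_id"] == 7]
        full = fl.train_response_model(anoms, seed=0, n_trees=N_TREES)
        excl = fl.train_response_model(anoms, exclude=window, seed=0,
                                       n_trees=N_TREES)
        other = anoms.data[anoms.data["in_season"]].drop(index=window)
        shift = (full.predict(other) - excl.predict(other)).abs()
        resid_sd = (other["gpp_anom"] - full.predict(other)).std()
        assert shift.mean() < resid_sd

    def test_gated_magnitude_not_larger_than_ungated(self, drought_site):
        series, truth = drought_site
        rc = fl.RunConfig(n_trees=N_TREES, seed=1)
        res = fl.process_site(series, rc)
        lr = res.legacy_results[0]
        assert abs(lr.normalized_gated_pct) <= abs(lr.normalized_ungated_pct) + 1e-9
        assert lr.sign == truth.legacy_sign
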