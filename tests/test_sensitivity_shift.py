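"""Attribution additivity, LOESS bands, response-curve overlap."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

import fluxlegacy as fl
from fluxlegacy.legacy import PREDICTORS, ResponseModel

from conftest import N_TREES


def _random_frame(rng, n=400):
    frame = pd.DataFrame(
        {p: rng.normal(0, 1, n) for p in PREDICTORS},
        index=pd.date_range("2000-01-01", periods=n, freq="D"),
    )
    frame["doy"] = frame.index.dayofyear
    return frame


def _fit_model(frame, y, n_trees=60, **kwargs):
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=0,
                               bootstrap=True, **kwargs)
    rf.fit(frame[list(PREDICTORS)].to_numpy(), y)
    return ResponseModel(model=rf, oob_score=0.0, n_training_days=len(frame))


class TestAttribution:
    def test_local_accuracy_exact(self, rng):
        frame = _random_frame(rng)
        y = np.sin(frame["sw_in_anom"]) + 0.5 * frame["ta_anom"] * frame["vpd_anom"]
        model = _fit_model(frame, y.to_numpy())
        attr, base = fl.attribution_values(model, frame)
        pred = model.predict(frame)
        resid = np.abs(attr.sum(axis=1) + base - pred)
        assert resid.max() < 1e-9

    def test_constant_target_gives_zero_attributions(self, rng):
        frame = _random_frame(rng)
        model = _fit_model(frame, np.full(len(frame), 3.3))
        attr, base = fl.attribution_values(model, frame)
        assert np.abs(attr.to_numpy()).max() < 1e-12
        assert base == pytest.approx(3.3)

    def test_single_predictor_attribution_equals_prediction_minus_base(self, rng):
        n = 300
        x = rng.normal(0, 1, n)
        frame = pd.DataFrame({"sw_in_anom": x},
                             index=pd.date_range("2000-01-01", periods=n))
        rf = RandomForestRegressor(n_estimators=40, random_state=0)
        rf.fit(x[:, None], np.tanh(x))
        model = ResponseModel(model=rf, oob_score=0.0, n_training_days=n,
                              predictors=("sw_in_anom",))
        attr, base = fl.attribution_values(model, frame)
        pred = model.predict(frame)
        np.testing.assert_allclose(attr["sw_in_anom"] + base, pred, atol=1e-9)

    def test_irrelevant_feature_gets_small_attribution(self, rng):
        frame = _random_frame(rng)
        y = 2.0 * frame["sw_in_anom"].to_numpy()
        model = _fit_model(frame, y)
        attr, _ = fl.attribution_values(model, frame)
        dominant = attr["sw_in_anom"].abs().mean()
        assert attr["wai_anom"].abs().mean() < 0.2 * dominant


class TestLoess:
    def test_recovers_straight_line(self, rng):
        x = rng.uniform(-2, 2, 200)
        y = 1.5 * x + 0.3 + rng.normal(0, 0.05, 200)
        grid = np.linspace(-1.5, 1.5, 50)
        fit, lo, hi = fl.loess_fit(x, y, grid)
        np.testing.assert_allclose(fit, 1.5 * grid + 0.3, atol=0.05)
        assert (lo < fit).all() and (fit < hi).all()

    def test_band_width_scales_with_noise(self, rng):
        x = rng.uniform(-2, 2, 200)
        grid = np.linspace(-1, 1, 20)
        _, lo1, hi1 = fl.loess_fit(x, rng.normal(0, 0.1, 200), grid)
        _, lo2, hi2 = fl.loess_fit(x, rng.normal(0, 1.0, 200), grid)
        assert np.mean(hi2 - lo2) > 5 * np.mean(hi1 - lo1)


class TestOverlap:
    def test_identical_clouds_full_overlap(self, rng):
        x = pd.Series(rng.uniform(-1, 1, 150), name="ta_anom")
        a = pd.Series(np.sin(x.to_numpy()) + rng.normal(0, 0.1, 150))
        res = fl.response_overlap(a, x, a.copy(), x.copy())
        assert res.overlap_pct == 100.0

    def test_separated_curves_no_overlap(self, rng):
        x1 = pd.Series(rng.uniform(-1, 1, 150), name="ta_anom")
        x2 = pd.Series(rng.uniform(-1, 1, 150), name="ta_anom")
        a1 = pd.Series(rng.normal(0, 0.05, 150))
        a2 = pd.Series(10.0 + rng.normal(0, 0.05, 150))
        res = fl.response_overlap(a1, x1, a2, x2)
        assert res.overlap_pct == 0.0

    def test_symmetric_in_period_order(self, rng):
        x1 = pd.Series(rng.uniform(-1, 1, 120), name="vpd_anom")
        x2 = pd.Series(rng.uniform(-1, 1, 120), name="vpd_anom")
        a1 = pd.Series(0.5 * x1.to_numpy() + rng.normal(0, 0.2, 120))
        a2 = pd.Series(-0.5 * x2.to_numpy() + rng.normal(0, 0.2, 120))
        r12 = fl.response_overlap(a1, x1, a2, x2)
        r21 = fl.response_overlap(a2, x2, a1, x1)
        assert r12.overlap_pct == pytest.approx(r21.overlap_pct)

    def test_too_few_points_returns_none(self, rng):
        x = pd.Series(rng.uniform(-1, 1, 10), name="ta_anom")
        a = pd.Series(rng.normal(0, 1, 10))
        assert fl.response_overlap(a, x, a, x) is None


class TestPeriodModels:
    def test_training_sets_size_matched_and_reproducible(self, drought_anoms,
                                                          drought_events):
        anoms = drought_anoms
        events, _ = drought_events
        sel = fl.select_events([e for e in events], record_years=12)
        dd = fl.pipeline.event_day_index(sel, anoms.data.index)
        season = anoms.data["season_id"] == sel[0].season_id
        window = anoms.data.index[season & (anoms.data.index > sel[0].end)]
        _, _, idx_l, idx_n = fl.fit_period_models(anoms, window, dd, seed=4,
                                                  n_trees=20)
        assert len(idx_l) == len(idx_n)
        _, _, _, idx_n2 = fl.fit_period_models(anoms, window, dd, seed=4,
                                               n_trees=20)
        assert idx_n.equals(idx_n2)

    def test_short_window_rejected(self, drought_anoms):
        anoms = drought_anoms
        window = anoms.data.index[anoms.data["in_season"]][:10]
        with pytest.raises(ValueError, match="too short"):
            fl.fit_period_models(anoms, window, pd.DatetimeIndex([]), seed=0,
                                 n_trees=20)

    def test_same_generating_response_high_overlap(self, rng):
        # both "periods" drawn from one response: curves indistinguishable
        overlaps = []
        for rep in range(5):
            x1 = pd.Series(rng.uniform(-2, 2, 150), name="sw_in_anom")
            x2 = pd.Series(rng.uniform(-2, 2, 150), name="sw_in_anom")
            f = lambda v: np.tanh(v)
            a1 = pd.Series(f(x1.to_numpy()) + rng.normal(0, 0.3, 150))
            a2 = pd.Series(f(x2.to_numpy()) + rng.normal(0, 0.3, 150))
            overlaps.append(fl.response_overlap(a1, x1, a2, x2).overlap_pct)
        assert np.median(overlaps) > 80.0
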