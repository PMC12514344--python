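"""EF droughts: flagging, event assembly, PET, SPEI, selection, concurrent."""

import numpy as np
import pandas as pd
import pytest

import fluxlegacy as fl
from fluxlegacy.drought_detection import merge_runs, _runs


def _series(values, start="2000-06-01"):
    idx = pd.date_range(start, periods=len(values), freq="D")
    return pd.Series(np.asarray(values, float), index=idx)


class TestEvaporativeFraction:
    @pytest.mark.parametrize(
        "le,h,expected", [(50, 50, 0.5), (100, 0, 1.0), (0, 100, 0.0)]
    )
    def test_values(self, le, h, expected):
        assert fl.evaporative_fraction([le], [h])[0] == expected

    def test_unrealistic_removed(self):
        out = fl.evaporative_fraction([-10.0, 120.0], [100.0, -20.0])
        assert np.isnan(out).all()

    def test_zero_denominator_missing(self):
        assert np.isnan(fl.evaporative_fraction([0.0], [0.0])[0])


class TestFlagging:
    def test_threshold_strictness(self, rng):
        base = rng.normal(0, 1.0, 5000)
        sigma = float(np.std(base))
        vals = np.concatenate([base, [-1.5 * sigma, -sigma]])
        flags, s = fl.flag_drought_days(_series(vals))
        assert flags.iloc[-2]            # below −σ → flagged
        assert not flags.iloc[-1]        # exactly −σ → strict inequality

    def test_standard_normal_flag_rate(self, rng):
        flags, _ = fl.flag_drought_days(_series(rng.normal(0, 1, 50_000)))
        assert flags.mean() == pytest.approx(0.159, abs=0.006)

    def test_zero_variance_fatal(self):
        with pytest.raises(ValueError):
            fl.flag_drought_days(_series(np.zeros(100)))

    def test_affine_invariance_of_flags(self, rng):
        vals = rng.normal(0, 1, 3000)
        f1, _ = fl.flag_drought_days(_series(vals))
        f2, _ = fl.flag_drought_days(_series(vals * 7.3))
        pd.testing.assert_series_equal(f1, f2)


def _assemble(flag_array, min_len=15, max_gap=3):
    flags = _series(flag_array).astype(bool)
    ef = _series(np.where(flag_array, -2.0, 0.5))
    seasons = np.zeros(len(flag_array), int)
    return fl.assemble_events(flags, ef, seasons, min_len=min_len, max_gap=max_gap)


class TestAssembleEvents:
    def test_single_long_run(self):
        events = _assemble(np.r_[np.zeros(5), np.ones(20), np.zeros(5)])
        assert len(events) == 1
        assert events[0].n_flagged == 20
        assert events[0].duration == 20

    def test_fourteen_days_insufficient(self):
        assert _assemble(np.r_[np.zeros(3), np.ones(14), np.zeros(3)]) == []

    def test_runs_merge_across_small_gap(self):
        arr = np.r_[np.ones(10), np.zeros(3), np.ones(8)]
        events = _assemble(arr)
        assert len(events) == 1
        assert events[0].n_flagged == 18
        assert events[0].duration == 21
        assert len(events[0].gap_days) == 3

    def test_gap_of_four_splits(self):
        arr = np.r_[np.ones(16), np.zeros(4), np.ones(16)]
        events = _assemble(arr)
        assert len(events) == 2

    def test_cumulative_ef_is_negative(self):
        events = _assemble(np.ones(20))
        assert events[0].cum_ef_anom == pytest.approx(-40.0)

    def test_events_confined_to_seasons(self):
        arr = np.ones(30)
        flags = _series(arr).astype(bool)
        ef = _series(np.full(30, -2.0))
        seasons = np.r_[np.zeros(15, int), np.ones(15, int)]
        events = fl.assemble_events(flags, ef, seasons, min_len=15, max_gap=3)
        assert len(events) == 2  # the run is split at the season boundary

    @pytest.mark.parametrize("min_len,max_gap", [(5, 0), (5, 3), (15, 1), (15, 3)])
    def test_brute_force_oracle(self, rng, min_len, max_gap):
        # merge-then-filter on explicit run lists, 200 random flag strings
        for _ in range(200):
            arr = (rng.random(rng.integers(20, 120)) < 0.45).astype(int)
            events = _assemble(arr, min_len=min_len, max_gap=max_gap)
            got = [(e.start, e.end, e.n_flagged) for e in events]
            runs = _runs(arr.astype(bool))
            merged = []
            for s, e in runs:
                if merged and s - merged[-1][1] - 1 <= max_gap:
                    merged[-1] = (merged[-1][0], e)
                else:
                    merged.append((s, e))
            idx = pd.date_range("2000-06-01", periods=len(arr), freq="D")
            expected = []
            for s, e in merged:
                n_fl = int(arr[s:e + 1].sum())
                if n_fl >= min_len:
                    expected.append((idx[s], idx[e], n_fl))
            assert got == expected

    def test_merge_runs_is_associative_on_chain(self):
        runs = [(0, 4), (7, 9), (13, 20)]
        assert merge_runs(runs, 2) == [(0, 9), (13, 20)]
        assert merge_runs(runs, 3) == [(0, 20)]


class TestPriestleyTaylor:
    def test_zero_available_energy(self):
        assert fl.priestley_taylor_pet(100.0, 20.0, g=100.0) == 0.0

    def test_hand_value(self):
        # R_n = 100 W m-2, 20 °C, G = 0: s = 0.14474 kPa/°C, γ = 0.067381,
        # λ = 2.45378 MJ/kg → 3.0273 mm d-1
        assert fl.priestley_taylor_pet(100.0, 20.0) == pytest.approx(3.0273, abs=2e-3)

    def test_monotone_in_temperature(self):
        cold = fl.priestley_taylor_pet(150.0, 5.0)
        warm = fl.priestley_taylor_pet(150.0, 25.0)
        assert warm > cold

    def test_negative_energy_clipped(self):
        assert fl.priestley_taylor_pet(-50.0, 10.0) == 0.0


@pytest.fixture(scope="module")
def climate():
    return fl.generate_stationary_climate(seed=21, years=25)


class TestSpei:

    def test_monotone_in_balance_within_pool(self, climate):
        p, pet = climate
        sp = fl.spei(p, pet)
        bal = (p - pet).rolling(90, min_periods=90).sum()
        doy = p.index.dayofyear
        sel = (doy == 200) & bal.notna() & sp.spei.notna()
        order_d = np.argsort(bal[sel].to_numpy())
        order_s = np.argsort(sp.spei[sel].to_numpy())
        np.testing.assert_array_equal(order_d, order_s)

    def test_driest_year_most_negative(self, climate):
        p, pet = climate
        sp = fl.spei(p, pet)
        bal = (p - pet).rolling(90, min_periods=90).sum()
        sel = (p.index.dayofyear == 210) & bal.notna()
        assert sp.spei[sel].idxmin() == bal[sel].idxmin()

    def test_first_window_days_missing(self, climate):
        p, pet = climate
        sp = fl.spei(p, pet)
        assert sp.spei.iloc[:89].isna().all()


class TestTraceability:
    def _spei_with_dip(self, dip_value, dip_day):
        idx = pd.date_range("2000-01-01", periods=400, freq="D")
        vals = np.zeros(400)
        vals[dip_day] = dip_value
        return fl.SpeiSeries(spei=pd.Series(vals, index=idx), window=90)

    def _event(self, start_day=200, end_day=230):
        idx = pd.date_range("2000-01-01", periods=400, freq="D")
        return fl.DroughtEvent(start=idx[start_day], end=idx[end_day],
                               season_id=0, n_flagged=20, cum_ef_anom=-10.0)

    def test_dip_inside_event(self):
        events = fl.traceability_filter([self._event()], self._spei_with_dip(-1.4, 210))
        assert events[0].spei_traceable

    def test_dip_in_lookback_window(self):
        events = fl.traceability_filter([self._event()], self._spei_with_dip(-1.2, 190))
        assert events[0].spei_traceable

    def test_dip_outside_lookback(self):
        events = fl.traceability_filter([self._event()], self._spei_with_dip(-1.2, 180))
        assert not events[0].spei_traceable

    def test_no_dip_not_traceable(self):
        events = fl.traceability_filter([self._event()], self._spei_with_dip(-0.8, 210))
        assert not events[0].spei_traceable


class TestSelection:
    def _events(self, cums, traceable=True):
        idx = pd.date_range("2000-01-01", periods=400, freq="D")
        return [
            fl.DroughtEvent(start=idx[10 + 50 * i], end=idx[30 + 50 * i],
                            season_id=i, n_flagged=20, cum_ef_anom=c,
                            spei_traceable=traceable)
            for i, c in enumerate(cums)
        ]

    def test_short_record_keeps_strongest_only(self):
        sel = fl.select_events(self._events([-30.0, -12.0]), record_years=10)
        assert [e.cum_ef_anom for e in sel] == [-30.0]
        assert sel[0].rank == 1

    def test_long_record_keeps_two(self):
        sel = fl.select_events(self._events([-12.0, -30.0]), record_years=15)
        assert [e.cum_ef_anom for e in sel] == [-30.0, -12.0]
        assert [e.rank for e in sel] == [1, 2]

    def test_single_event(self):
        sel = fl.select_events(self._events([-9.0]), record_years=20)
        assert len(sel) == 1

    def test_untraceable_excluded(self):
        sel = fl.select_events(self._events([-30.0], traceable=False), record_years=10)
        assert sel == []


class TestConcurrentEffect:
    def test_ratio(self, drought_anoms, drought_events):
        events, _ = drought_events
        traceable = [e for e in events if e.spei_traceable]
        ce = fl.concurrent_effect(traceable[0], drought_anoms)
        expected = 100.0 * ce.cum_gpp_anom / drought_anoms.gs_mean_total_gpp
        assert ce.normalized_pct == pytest.approx(expected)
        assert ce.normalized_pct < 0

    def test_zero_anomalies_give_zero(self, drought_anoms):
        anoms = drought_anoms
        ev = fl.DroughtEvent(
            start=anoms.data.index[30], end=anoms.data.index[40],
            season_id=0, n_flagged=11, cum_ef_anom=-5.0)
        import copy
        silent = copy.copy(anoms)
        silent.data = anoms.data.copy()
        silent.data["gpp_gapfilled_anom"] = 0.0
        assert fl.concurrent_effect(ev, silent).normalized_pct == 0.0
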