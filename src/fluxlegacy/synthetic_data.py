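"""Synthetic daily flux-site records with known droughts and legacy effects.

The generator emulates a temperate flux site: sinusoidal seasonal cycles in
radiation, temperature and VPD with AR(1) weather noise, marked-Bernoulli
rainfall, a single-bucket soil store that couples evapotranspiration (hence
the evaporative fraction) and GPP to water availability, and optional imposed
droughts (precipitation suppression leading an EF depression of configurable
σ-depth, with a concurrent GPP reduction) and post-drought legacy effects
(multiplicative GPP offsets over configured growing seasons).  The imposed
truth is returned alongside the record so every pipeline stage can be tested
against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io_fluxnet import SiteTimeSeries
from .water_balance import latent_heat_of_vaporization, SECONDS_PER_DAY

PEAK_DOY = 196  # mid-July seasonal peak


@dataclass
class DroughtSpec:
    """One imposed drought: EF depression window plus leading rain deficit.

    Rain is suppressed from ``precip_lead`` days before the EF window until
    ``recovery_days`` before its end, so the soil store is recharging again
    when the event closes and the drought does not smear into the post-event
    period that the legacy analysis inspects.
    """

    year_index: int = 6
    start_doy: int = 172
    length: int = 30
    precip_suppression: float = 0.95
    precip_lead: int = 25
    recovery_days: int = 10
    ef_depression_sigma: float = 2.0
    gpp_reduction: float = 0.35


@dataclass
class LegacySpec:
    """Imposed post-drought legacy: multiplicative GPP offset.

    ``duration_seasons=1`` spans the drought-year growing season after the
    event; larger values extend over subsequent whole growing seasons.
    ``shape`` is ``"constant"`` (same offset throughout) or ``"linear"``
    (offset decays linearly to zero over the seasons).
    """

    magnitude: float = -0.15
    duration_seasons: int = 1
    shape: str = "constant"


@dataclass
class SyntheticConfig:
    """Generator settings; defaults describe a 12-year temperate site."""

    years: int = 12
    start_year: int = 2000
    site_id: str = "SYN-000"
    seed: int = 0
    # seasonal driver climatology
    gmax: float = 10.0          # peak clean GPP, gC m-2 d-1
    ta_mean: float = 9.0        # °C
    ta_amp: float = 11.0
    sw_base: float = 40.0       # W m-2
    sw_amp: float = 320.0
    vpd_base: float = 1.5       # hPa
    vpd_amp: float = 8.0
    # AR(1) weather noise
    ar1_phi: float = 0.5
    ta_noise_sd: float = 1.8
    sw_noise_sd: float = 35.0
    vpd_noise_sd: float = 1.0
    gpp_noise_sd: float = 0.9
    le_noise_rel_sd: float = 0.10   # day-to-day relative LE measurement noise
    # water cycle
    rain_prob: float = 0.5
    rain_mean_mm: float = 8.0
    bucket_capacity: float = 50.0
    et_demand: float = 3.2      # peak atmospheric demand, mm d-1
    # data quality and trends
    qc_dropout: float = 0.02
    trend_slopes: dict = field(default_factory=dict)  # var -> units per day
    # imposed signals
    droughts: list = field(default_factory=list)
    legacy: LegacySpec | None = None


@dataclass
class SyntheticTruth:
    """Imposed signals, serialized next to the generated record."""

    drought_windows: list  # [(start, end)] timestamps of EF-depression windows
    concurrent_pct: list   # imposed concurrent effect per drought, % of GS GPP
    legacy_windows: list   # [(start, end)] per legacy season
    legacy_magnitude: float | None
    legacy_duration_seasons: int
    legacy_sign: str       # "negative" | "positive" | "none"
    gs_mean_total_gpp: float
    trend_slopes: dict

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drought_windows"] = [(str(a), str(b)) for a, b in self.drought_windows]
        d["legacy_windows"] = [(str(a), str(b)) for a, b in self.legacy_windows]
        return d


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    e = rng.normal(0.0, sd * np.sqrt(max(1e-12, 1 - phi**2)), n)
    return lfilter([1.0], [1.0, -phi], e)


def _drought_window(cfg: SyntheticConfig, spec: DroughtSpec,
                    index: pd.DatetimeIndex) -> pd.DatetimeIndex:
    year = cfg.start_year + spec.year_index
    start = pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(days=spec.start_doy - 1)
    end = start + pd.Timedelta(days=spec.length - 1)
    return index[(index >= start) & (index <= end)]


def generate_site(config: SyntheticConfig) -> tuple[SiteTimeSeries, SyntheticTruth]:
    """Generate one synthetic site record plus its imposed truth.

    Deterministic for a fixed config seed.  Raises when an imposed legacy
    extends beyond the record end.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    index = pd.date_range(
        start=f"{cfg.start_year}-01-01",
        end=f"{cfg.start_year + cfg.years - 1}-12-31",
        freq="D",
    )
    n = len(index)
    doy = index.dayofyear.to_numpy()
    years = index.year.to_numpy()
    phase = np.cos(2 * np.pi * (doy - PEAK_DOY) / 365.25)
    s = 0.5 * (1.0 + phase)          # 0 (midwinter) .. 1 (peak)
    env = s**2                       # GPP seasonal envelope; GS where s > 0.5
    in_gs = s > 0.5

    ta = cfg.ta_mean + cfg.ta_amp * (2 * s - 1) + _ar1(rng, n, cfg.ar1_phi, cfg.ta_noise_sd)
    sw = np.clip(cfg.sw_base + cfg.sw_amp * s + _ar1(rng, n, cfg.ar1_phi, cfg.sw_noise_sd), 2.0, None)
    vpd = np.clip(cfg.vpd_base + cfg.vpd_amp * s + 0.25 * (ta - (cfg.ta_mean + cfg.ta_amp * (2 * s - 1)))
                  + _ar1(rng, n, cfg.ar1_phi, cfg.vpd_noise_sd), 0.05, None)

    # rainfall, with imposed suppression windows leading each EF drought;
    # the unsuppressed series is kept for the counterfactual truth
    wet = rng.random(n) < cfg.rain_prob
    precip_base = np.where(wet, rng.exponential(cfg.rain_mean_mm, n), 0.0)
    precip = precip_base.copy()
    for spec in cfg.droughts:
        win = _drought_window(cfg, spec, index)
        if len(win) == 0:
            raise ValueError("imposed drought lies outside the record")
        lead_start = win[0] - pd.Timedelta(days=spec.precip_lead)
        supp_end = win[-1] - pd.Timedelta(days=spec.recovery_days)
        sel = (index >= lead_start) & (index <= supp_end)
        precip[sel] *= 1.0 - spec.precip_suppression

    # single-bucket soil store coupling ET and GPP to water availability
    cap = cfg.bucket_capacity
    demand = cfg.et_demand * (0.35 + 0.65 * s)
    # available energy follows the smooth seasonal radiation; day-to-day
    # radiation noise is shed as sensible heat, so EF reflects water supply
    # and measurement noise rather than cloudiness
    avail_energy = 0.5 * (cfg.sw_base + cfg.sw_amp * s) + 30.0  # W m-2
    lam = latent_heat_of_vaporization(ta)
    et_energy_cap = 0.95 * avail_energy * SECONDS_PER_DAY / lam  # mm d-1

    def _soil(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        w = np.empty(n)
        et = np.empty(n)
        store = 0.8 * cap
        for i in range(n):
            # ET becomes supply-limited only when the store runs low, so the
            # evaporative fraction collapses in severe droughts but is
            # otherwise energy-limited
            supply = np.clip(store / (0.25 * cap), 0.0, 1.0)
            et[i] = min(demand[i] * supply, et_energy_cap[i])
            store = min(cap, max(0.0, store + p[i] - et[i]))
            w[i] = store
        return w, et

    w, et = _soil(precip)
    w_base, _ = _soil(precip_base)

    le = et * lam / SECONDS_PER_DAY
    # day-to-day flux measurement noise keeps EF anomalies from inheriting
    # the full multi-week soil-moisture memory (and keeps EF inside (0, 1))
    eta = np.clip(rng.normal(0.0, cfg.le_noise_rel_sd, n), -0.35, 0.35)
    le = np.clip(le * (1.0 + eta), 0.0, 0.98 * avail_energy)
    ef = le / avail_energy

    # EF depression: pin drought-day EF below its climatology by k·σ
    drought_windows: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    drought_mask = np.zeros(n, bool)
    for spec in cfg.droughts:
        win = _drought_window(cfg, spec, index)
        drought_mask |= index.isin(win)
        drought_windows.append((win[0], win[-1]))
    if cfg.droughts:
        ef_clim = pd.Series(ef[~drought_mask], index=index[~drought_mask])
        cycle = ef_clim.groupby(ef_clim.index.dayofyear).mean()
        cyc = np.full(367, np.nan)
        cyc[cycle.index.to_numpy()] = cycle.to_numpy()
        anom = ef - cyc[doy]
        sigma_ef = float(np.nanstd(anom[in_gs & ~drought_mask]))
        for spec in cfg.droughts:
            win_mask = index.isin(_drought_window(cfg, spec, index))
            target = np.clip(cyc[doy] - spec.ef_depression_sigma * sigma_ef, 0.02, 0.98)
            # cap, don't replace: where the drained store has already pushed
            # EF below the target the mechanistic flux stands, so the water
            # balance seen by a bucket reconstruction from LE stays honest
            le = np.where(win_mask, np.minimum(le, target * avail_energy), le)
        et = le * SECONDS_PER_DAY / lam
        ef = le / avail_energy
    h = avail_energy - le

    # clean GPP from smooth, monotone responses to the same drivers; the
    # water down-regulation is a gentle ramp (an energy-limited site: even a
    # deep drought costs at most ~12% through this pathway)
    light = sw / (sw + 120.0)
    tfun = np.exp(-(((ta - 18.0) / 14.0) ** 2))
    vfun = np.clip(1.1 - 0.045 * vpd, 0.3, 1.0)

    def _wfun(wv: np.ndarray) -> np.ndarray:
        return np.clip(0.88 + 0.12 * wv / (0.9 * cap), 0.88, 1.0)

    # GPP couples to the *undisturbed* soil store: the imposed drought reaches
    # GPP only through its explicit reduction factor, so the imposed
    # concurrent truth is exact, while natural water variability still gives
    # the response model a real GPP–WAI dependence to learn.  The disturbed
    # store drives LE/EF (and hence the pipeline's WAI), so the drought's
    # hydrological footprint is fully present in the detectable signals.
    gpp_response = cfg.gmax * env * light * tfun * vfun * 2.2
    gpp_clean = gpp_response * _wfun(w_base)

    # imposed concurrent reductions
    multiplier = np.ones(n)
    for spec in cfg.droughts:
        win_mask = index.isin(_drought_window(cfg, spec, index))
        multiplier[win_mask] *= 1.0 - spec.gpp_reduction

    # imposed legacy seasons
    legacy_windows: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    legacy_sign = "none"
    if cfg.legacy is not None and cfg.droughts:
        spec = cfg.droughts[0]
        end = drought_windows[0][1]
        drought_year = cfg.start_year + spec.year_index
        for j in range(cfg.legacy.duration_seasons):
            season_year = drought_year + j
            if season_year > cfg.start_year + cfg.years - 1:
                raise ValueError("imposed legacy extends beyond the record end")
            sel = in_gs & (years == season_year)
            if j == 0:
                sel = sel & (index > end)
            if not sel.any():
                raise ValueError("imposed legacy season has no growing-season days")
            if cfg.legacy.shape == "linear":
                m = cfg.legacy.magnitude * (cfg.legacy.duration_seasons - j) / cfg.legacy.duration_seasons
            else:
                m = cfg.legacy.magnitude
            multiplier[sel] *= 1.0 + m
            days = index[sel]
            legacy_windows.append((days[0], days[-1]))
        legacy_sign = "negative" if cfg.legacy.magnitude < 0 else "positive"

    noise = rng.normal(0.0, cfg.gpp_noise_sd, n) * (0.3 + 0.7 * env)
    gpp = gpp_clean * multiplier + noise

    # linear trends (added after everything else, removable by detrending)
    t = np.arange(n, dtype=float)
    columns = {"gpp": gpp, "le": le, "h": h, "ta": ta, "vpd": vpd,
               "sw_in": sw, "netrad": avail_energy, "precip": precip}
    for var, slope in cfg.trend_slopes.items():
        columns[var] = columns[var] + slope * t

    data = pd.DataFrame(columns, index=pd.DatetimeIndex(index, name="date"))
    for var in ("gpp", "le", "h", "ta", "vpd", "sw_in"):
        qc = np.ones(n)
        bad = rng.random(n) < cfg.qc_dropout
        qc[bad] = rng.uniform(0.0, 0.65, bad.sum())
        data[f"qc_{var}"] = qc

    # imposed truth, measured on the clean (noise-free) series
    gs_totals = pd.Series(np.where(in_gs, gpp_clean, 0.0), index=index)
    per_year = gs_totals.groupby(years).sum()
    gs_mean_total = float(per_year.mean())
    concurrent_pct = []
    for spec, (start, end) in zip(cfg.droughts, drought_windows):
        win_mask = (index >= start) & (index <= end)
        imposed = -spec.gpp_reduction * float(np.sum(gpp_clean[win_mask]))
        concurrent_pct.append(100.0 * imposed / gs_mean_total)

    truth = SyntheticTruth(
        drought_windows=drought_windows,
        concurrent_pct=concurrent_pct,
        legacy_windows=legacy_windows,
        legacy_magnitude=None if cfg.legacy is None else cfg.legacy.magnitude,
        legacy_duration_seasons=0 if cfg.legacy is None else cfg.legacy.duration_seasons,
        legacy_sign=legacy_sign,
        gs_mean_total_gpp=gs_mean_total,
        trend_slopes=dict(cfg.trend_slopes),
    )
    return SiteTimeSeries(site_id=cfg.site_id, data=data), truth


# ---------------------------------------------------------------------------
# Stationary calibration climate
# ---------------------------------------------------------------------------

def generate_stationary_climate(
    seed: int = 0,
    years: int = 40,
    tau: float = 0.35,
    regime_phi: float = 0.995,
    rain_prob: float = 0.6,
    daily_net_mean: float = 2.0,
) -> tuple[pd.Series, pd.Series]:
    """Stationary daily (P, PET) pair for standardized-index calibration.

    A slowly varying intensity regime (log-AR(1) with ~200-day memory)
    multiplies both rainfall amounts and atmospheric demand, so the mean
    water balance stays zero while its variance wanders — wet-intense and
    calm hydroclimate phases.  Aggregated balances are then a scale mixture
    of near-Gaussian sums, i.e. symmetric with mildly heavy tails, which is
    squarely inside the reach of the log-logistic family the index fits;
    with no seasonal cycle every calendar-day pool shares one distribution.
    """
    rng = np.random.default_rng(seed)
    idx = pd.date_range("1980-01-01", periods=365 * years, freq="D")
    n = len(idx)
    z = lfilter([1.0], [1.0, -regime_phi],
                rng.normal(0, np.sqrt(1 - regime_phi**2), n))
    scale = np.exp(tau * z)
    amounts = rng.exponential(daily_net_mean / rain_prob, n) * scale
    p = pd.Series(np.where(rng.random(n) < rain_prob, amounts, 0.0), index=idx)
    pet = pd.Series(
        np.clip(daily_net_mean * scale + rng.normal(0, 0.3, n), 0, None),
        index=idx,
    )
    return p, pet


# ---------------------------------------------------------------------------
# Synthetic driver tables
# ---------------------------------------------------------------------------

DEFAULT_DRIVERS = (
    "forest",
    "drought_duration",
    "aridity",
    "pre_drought_water_limitation",
)


def default_effect_map() -> dict:
    """One truly dependent driver: stronger pre-drought water limitation
    (more negative index) drives a more negative legacy effect."""
    return {"pre_drought_water_limitation": lambda x: -4.0 * x}


def generate_driver_table(
    n_events: int = 26,
    effect_map: dict | None = None,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-event driver table with a known set of dependent drivers.

    Drivers: a binary forest indicator, drought duration (days, matching the
    observed 35 ± 24 spread), and standardized aridity and pre-drought water
    limitation.  The legacy-effect column is the sum of the
    mapped effects plus Gaussian noise; drivers not in ``effect_map`` are
    independent of it by construction.  The driver set is deliberately small:
    at a couple dozen events the family-wise chance of a false 2-of-3
    candidate grows with every extra null driver tested (each calibrated
    test rejects ~5% of independent drivers, so a table of k null drivers
    yields a clean screen only ~0.95^k of the time).  Returns the table
    and the list of truly dependent driver names.
    """
    if n_events < 20:
        raise ValueError("need at least 20 events for stable kernel tests")
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {
            "forest": rng.integers(0, 2, n_events).astype(float),
            "drought_duration": np.clip(rng.normal(35, 24, n_events), 15, None),
            "aridity": rng.normal(0, 1, n_events),
            "pre_drought_water_limitation": rng.normal(0, 1, n_events),
        }
    )
    effects = default_effect_map() if effect_map is None else effect_map
    legacy = rng.normal(0.0, noise_sd, n_events)
    for name, fn in effects.items():
        legacy = legacy + fn(table[name].to_numpy())
    table["legacy_effect"] = legacy
    return table, sorted(effects.keys())
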