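"""Impact-drought detection from evaporative-fraction anomalies.

A day is in drought when its EF anomaly falls below −1σ of the growing-season
record; runs of flagged days (gaps < 4 days bridged, at least 15 flagged days)
form events; events must be traceable to a meteorological drought (SPEI₉₀
below −1 during the event or the preceding 15 days); per site the strongest
event by cumulative EF anomaly is kept (plus the second strongest for records
of 14+ years).  Concurrent effects are cumulative gap-filled GPP anomalies
over the event, normalized by the long-term mean total growing-season GPP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .water_balance import SECONDS_PER_DAY, latent_heat_of_vaporization
from .preprocessing import AnomalySeries

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Evaporative fraction
# ---------------------------------------------------------------------------

def evaporative_fraction(le, h) -> np.ndarray:
    """EF = LE/(LE + H), with unphysical values (<0 or >1) set missing.

    EF is the share of turbulent energy used for evaporation; it declines as
    water limitation forces the surface to shed energy as sensible heat.
    LE + H = 0 yields missing.
    """
    le = np.asarray(le, float)
    h = np.asarray(h, float)
    denom = le + h
    with np.errstate(divide="ignore", invalid="ignore"):
        ef = np.where(denom != 0, le / denom, np.nan)
    ef[(ef < 0) | (ef > 1)] = np.nan
    return ef


def flag_drought_days(ef_anom: pd.Series, k: float = 1.0) -> tuple[pd.Series, float]:
    """Flag days with EF anomaly strictly below −k·σ.

    σ is the standard deviation of all (growing-season) EF anomalies in the
    record; the anomaly must be *below* the threshold, so a value exactly at
    −σ is not flagged.  Returns the boolean series and σ.
    """
    if k <= 0:
        raise ValueError("sigma multiplier must be positive")
    vals = ef_anom.to_numpy(float)
    sigma = float(np.nanstd(vals, ddof=0))
    if not np.isfinite(sigma) or sigma == 0:
        raise ValueError("EF anomaly variance is zero; cannot define droughts")
    flags = pd.Series(vals < -k * sigma, index=ef_anom.index)
    flags[~np.isfinite(vals)] = False
    return flags, sigma


# ---------------------------------------------------------------------------
# Event assembly
# ---------------------------------------------------------------------------

@dataclass
class DroughtEvent:
    """A contiguous low-EF episode inside one growing season."""

    start: pd.Timestamp
    end: pd.Timestamp
    season_id: int
    n_flagged: int
    cum_ef_anom: float
    gap_days: list[pd.Timestamp] = field(default_factory=list)
    spei_traceable: bool | None = None
    rank: int | None = None

    @property
    def duration(self) -> int:
        """Calendar span in days, start and end inclusive."""
        return int((self.end - self.start).days) + 1


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) inclusive index pairs of True runs."""
    out = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(mask) - 1))
    return out


def merge_runs(
    runs: list[tuple[int, int]], max_gap: int
) -> list[tuple[int, int]]:
    """Merge runs separated by gaps of at most ``max_gap`` unflagged days."""
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe - 1 <= max_gap:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def assemble_events(
    flags: pd.Series,
    ef_anom: pd.Series,
    season_ids: np.ndarray,
    min_len: int = 15,
    max_gap: int = 3,
    min_len_on: str = "flagged",
) -> list[DroughtEvent]:
    """Assemble drought events from per-day flags within growing seasons.

    Flagged runs separated by fewer than ``max_gap + 1`` unflagged days merge
    into one episode; an episode qualifies when it holds at least ``min_len``
    flagged days (``min_len_on="span"`` counts calendar span instead).
    Episodes never cross a growing-season boundary — a run reaching the
    season edge ends there.  Cumulative EF anomaly sums the flagged days
    (each below −σ), so it is strictly negative.
    """
    events: list[DroughtEvent] = []
    for season in np.unique(season_ids[season_ids >= 0]):
        sel = season_ids == season
        idx = flags.index[sel]
        f = flags.to_numpy()[sel]
        merged = merge_runs(_runs(f), max_gap)
        for s, e in merged:
            flagged_pos = np.nonzero(f[s:e + 1])[0] + s
            size = len(flagged_pos) if min_len_on == "flagged" else e - s + 1
            if size < min_len:
                continue
            gap_days = [idx[i] for i in range(s, e + 1) if not f[i]]
            cum = float(np.nansum(ef_anom.loc[idx[s]:idx[e]].to_numpy()[f[s:e + 1]]))
            events.append(
                DroughtEvent(
                    start=idx[s], end=idx[e], season_id=int(season),
                    n_flagged=int(len(flagged_pos)), cum_ef_anom=cum,
                    gap_days=gap_days,
                )
            )
    return events


# ---------------------------------------------------------------------------
# Priestley–Taylor PET and daily SPEI
# ---------------------------------------------------------------------------

PT_ALPHA = 1.26
PSYCHROMETRIC_KPA = 0.665e-3 * 101.325  # γ at standard pressure, kPa °C⁻¹


def saturation_vapor_pressure_slope(ta_c) -> np.ndarray:
    """Slope s of the saturation vapor pressure curve (kPa °C⁻¹) at T (°C)."""
    ta = np.asarray(ta_c, float)
    es = 0.6108 * np.exp(17.27 * ta / (ta + 237.3))
    return 4098.0 * es / (ta + 237.3) ** 2


def priestley_taylor_pet(netrad, ta, g=0.0) -> np.ndarray:
    """Priestley–Taylor potential evapotranspiration (mm d⁻¹).

    λ·PET = 1.26 · s/(s+γ) · (R_n − G), with R_n and G in W m⁻², s from the
    Clausius–Clapeyron relation at air temperature, γ the psychrometric
    constant at standard pressure, and λ(T) converting energy to water depth.
    G defaults to 0 at the daily scale; negative available energy clips PET
    at 0.
    """
    rn = np.asarray(netrad, float)
    s = saturation_vapor_pressure_slope(ta)
    lam = latent_heat_of_vaporization(ta)
    energy = np.clip(rn - np.asarray(g, float), 0.0, None) * SECONDS_PER_DAY
    return PT_ALPHA * s / (s + PSYCHROMETRIC_KPA) * energy / lam


def _unbiased_pwms(sorted_x: np.ndarray) -> tuple[float, float, float]:
    """Unbiased probability-weighted moments b0, b1, b2 of an ascending sample."""
    n = sorted_x.size
    i = np.arange(1, n + 1, dtype=float)
    b0 = sorted_x.mean()
    b1 = np.sum((i - 1) / (n - 1) * sorted_x) / n
    b2 = np.sum((i - 1) * (i - 2) / ((n - 1) * (n - 2)) * sorted_x) / n
    return float(b0), float(b1), float(b2)


def _loglogistic_fit(x: np.ndarray) -> tuple[float, float, float] | None:
    """Fit the 3-parameter log-logistic distribution by unbiased PWMs.

    Uses the generalized-logistic (Hosking) parameterization of the shifted
    log-logistic: L-moments λ1, λ2, τ3 from the unbiased PWMs give shape
    k = −τ3, scale α = λ2·sin(πk)/(πk) and location ξ.  Returns
    (xi, alpha, k) or None when the sample admits no valid fit.
    """
    x = np.sort(x[np.isfinite(x)])
    if x.size < 10 or np.ptp(x) == 0:
        return None
    b0, b1, b2 = _unbiased_pwms(x)
    lam1 = b0
    lam2 = 2.0 * b1 - b0
    lam3 = 6.0 * b2 - 6.0 * b1 + b0
    if lam2 <= 0:
        return None
    tau3 = lam3 / lam2
    k = -tau3
    if abs(k) >= 0.95:  # too skewed for a usable GLO fit
        return None
    if abs(k) < 1e-9:
        alpha = lam2
        xi = lam1
    else:
        alpha = lam2 * np.sin(np.pi * k) / (np.pi * k)
        xi = lam1 - alpha * (1.0 / k - np.pi / np.sin(np.pi * k))
    if not np.isfinite(alpha) or alpha <= 0:
        return None
    return float(xi), float(alpha), float(k)


def _loglogistic_cdf(x: np.ndarray, xi: float, alpha: float, k: float) -> np.ndarray:
    """CDF of the generalized-logistic / shifted log-logistic distribution."""
    x = np.asarray(x, float)
    if abs(k) < 1e-9:
        y = (x - xi) / alpha
    else:
        arg = 1.0 - k * (x - xi) / alpha
        y = np.full(x.shape, np.nan)
        ok = arg > 0
        y[ok] = -np.log(arg[ok]) / k
        # beyond the bounded tail: below the lower bound (k<0) the CDF is 0,
        # above the upper bound (k>0) it is 1
        y[~ok & np.isfinite(x)] = -np.inf if k < 0 else np.inf
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-y))


@dataclass
class SpeiSeries:
    """Daily standardized precipitation–evapotranspiration index."""

    spei: pd.Series
    window: int
    pet: pd.Series | None = None


def spei(
    p: pd.Series,
    pet: pd.Series,
    window: int = 90,
    pool_halfwidth: int = 5,
    prob_clip: float = 1e-6,
) -> SpeiSeries:
    """Daily SPEI: standardized trailing-``window`` sums of P − PET.

    For each calendar day the climatic balance D (trailing 90-day sum by
    default) is pooled across years within ±``pool_halfwidth`` days (circular
    over the year boundary) and fitted with a 3-parameter log-logistic
    distribution by unbiased probability-weighted moments; SPEI is the
    standard-normal quantile of the fitted CDF.  Pools whose fit fails yield
    missing SPEI for that calendar day (logged).  The pool half-width trades
    fit stability against seasonal-gradient leakage: where the PET cycle is
    strong, wide pools mix climatologically different days and damp real
    anomalies, so the default stays narrow.
    """
    if not p.index.equals(pet.index):
        raise ValueError("P and PET must share an index")
    balance = (p - pet).rolling(window=window, min_periods=window).sum()
    d = balance.to_numpy(float)
    doy = p.index.dayofyear.to_numpy()

    n_doy = 366
    spei_vals = np.full(d.size, np.nan)
    failures = 0
    for day in range(1, n_doy + 1):
        targets = np.nonzero(doy == day)[0]
        if targets.size == 0:
            continue
        lo = (doy - day + 183) % 366 - 183  # circular DOY distance
        pool = d[(np.abs(lo) <= pool_halfwidth) & np.isfinite(d)]
        params = _loglogistic_fit(pool)
        if params is None:
            failures += 1
            continue
        probs = _loglogistic_cdf(d[targets], *params)
        probs = np.clip(probs, prob_clip, 1.0 - prob_clip)
        spei_vals[targets] = stats.norm.ppf(probs)
    if failures:
        log.warning("SPEI fit failed for %d calendar-day pools", failures)
    return SpeiSeries(spei=pd.Series(spei_vals, index=p.index, name="spei"),
                      window=window, pet=pet)


# ---------------------------------------------------------------------------
# Traceability, selection, concurrent effect
# ---------------------------------------------------------------------------

def traceability_filter(
    events: list[DroughtEvent],
    spei_series: SpeiSeries,
    threshold: float = -1.0,
    lookback: int = 15,
) -> list[DroughtEvent]:
    """Mark events traceable to a meteorological drought.

    An event is traceable when SPEI drops below ``threshold`` on at least one
    day between ``lookback`` days before its start and its end — the lag
    allows the ecosystem response to trail the meteorological deficit.
    Events with no SPEI coverage over that window are dropped (logged).
    """
    kept: list[DroughtEvent] = []
    for ev in events:
        lo = ev.start - pd.Timedelta(days=lookback)
        vals = spei_series.spei.loc[lo:ev.end].to_numpy(float)
        if not np.isfinite(vals).any():
            log.warning("event %s–%s dropped: no SPEI coverage",
                        ev.start.date(), ev.end.date())
            continue
        ev.spei_traceable = bool(np.nanmin(vals) < threshold)
        kept.append(ev)
    return kept


def select_events(
    events: list[DroughtEvent],
    record_years: int,
    second_event_min_years: int = 14,
) -> list[DroughtEvent]:
    """Rank traceable events by cumulative EF anomaly and keep the strongest.

    The strongest drought (most negative cumulative EF anomaly) is analyzed
    at every site; records of ``second_event_min_years`` or more also
    contribute their second strongest event.  Returns an empty list when no
    traceable events exist (the site is then excluded from legacy analysis).
    """
    traceable = [e for e in events if e.spei_traceable]
    traceable.sort(key=lambda e: e.cum_ef_anom)
    n_keep = 2 if record_years >= second_event_min_years else 1
    selected = traceable[:n_keep]
    for rank, ev in enumerate(selected, start=1):
        ev.rank = rank
    return selected


@dataclass
class ConcurrentEffect:
    """Cumulative gap-filled GPP anomaly over a drought event."""

    cum_gpp_anom: float
    normalized_pct: float


def concurrent_effect(
    event: DroughtEvent, anoms: AnomalySeries
) -> ConcurrentEffect:
    """Cumulative GPP anomaly over the event span, as % of mean seasonal GPP.

    Uses the gap-filled GPP channel over the full event span (gap days
    included) so quality-control holes cannot bias the cumulative sum;
    normalization is by the long-term mean total growing-season GPP.
    """
    window = anoms.data.loc[event.start:event.end]
    cum = float(np.nansum(window["gpp_gapfilled_anom"].to_numpy()))
    normalized = 100.0 * cum / anoms.gs_mean_total_gpp
    return ConcurrentEffect(cum_gpp_anom=cum, normalized_pct=normalized)
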