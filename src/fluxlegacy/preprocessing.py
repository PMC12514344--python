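"""Growing-season determination, detrending, deseasonalizing, anomalies.

The analysis operates on daily anomalies inside the growing season: each
variable is detrended (only when the Mann–Kendall test on annual means finds a
significant monotone trend), then deseasonalized by subtracting the per-DOY
mean cycle computed from the detrended record.  The growing season is the set
of DOYs where the 7-day-smoothed mean GPP cycle exceeds a fraction of its
maximum (25% by default, 10% for sites with bimodal or cross-year seasons).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

N_DOY = 366


# ---------------------------------------------------------------------------
# Mann–Kendall trend test (tie-corrected normal approximation)
# ---------------------------------------------------------------------------

def mann_kendall(x: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Kendall trend test.

    Returns ``(S, p)`` where ``S = sum_{i<j} sign(x_j - x_i)`` and ``p`` uses
    the normal approximation with the tie-corrected variance and a continuity
    correction.  Intended for short annual-mean series.
    """
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 3:
        return 0.0, 1.0
    s = 0.0
    for i in range(n - 1):
        s += np.sign(x[i + 1:] - x[i]).sum()
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var <= 0:
        return float(s), 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var)
    elif s < 0:
        z = (s + 1) / np.sqrt(var)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return float(s), float(p)


def _sens_slope(t: np.ndarray, y: np.ndarray) -> float:
    """Median of pairwise slopes (Theil–Sen), for the alternative estimator."""
    res = stats.theilslopes(y, t)
    return float(res.slope)


def detrend(
    values: pd.Series, alpha: float = 0.05, method: str = "ols"
) -> tuple[pd.Series, float]:
    """Remove a significant long-term linear trend from a daily series.

    The Mann–Kendall test runs on calendar-year means (daily data would
    inflate significance through seasonal autocorrelation).  If p < ``alpha``
    the linear fit against time is subtracted (slope per day, record mean
    preserved); otherwise the series is returned unchanged with slope 0.
    ``method`` selects the slope estimator: ``"ols"`` (default) or ``"sen"``.
    Idempotent: the detrended series has no remaining significant trend slope.
    """
    annual = values.groupby(values.index.year).mean()
    _, p = mann_kendall(annual.to_numpy())
    if p >= alpha or annual.notna().sum() < 3:
        return values.copy(), 0.0
    mask = values.notna().to_numpy()
    t = np.arange(len(values), dtype=float)
    y = values.to_numpy(float)
    if mask.sum() < 3:
        return values.copy(), 0.0
    if method == "sen":
        slope = _sens_slope(t[mask], y[mask])
    else:
        slope, _ = np.polyfit(t[mask], y[mask], 1)
    out = values - slope * (t - t[mask].mean())
    return out, float(slope)


# ---------------------------------------------------------------------------
# Seasonal cycle and growing season
# ---------------------------------------------------------------------------

@dataclass
class SeasonalCycle:
    """Per-DOY mean of a daily variable plus its 7-day smoothed variant.

    Arrays have 366 entries (index = DOY − 1); DOYs never observed are NaN.
    Smoothing is circular on the DOY wheel (Dec 29 neighbours Jan 2), so the
    cycle has no edge artefacts at the year boundary.
    """

    mean: np.ndarray
    smoothed: np.ndarray

    def at_doy(self, doy: np.ndarray) -> np.ndarray:
        return self.mean[np.asarray(doy, int) - 1]


def mean_seasonal_cycle(values: pd.Series, smooth_window: int = 7) -> SeasonalCycle:
    """Mean of each day-of-year across all years, with a circular moving average."""
    doy = values.index.dayofyear
    mean = np.full(N_DOY, np.nan)
    grouped = values.groupby(doy).mean()
    mean[grouped.index.to_numpy() - 1] = grouped.to_numpy()

    half = smooth_window // 2
    smoothed = np.full(N_DOY, np.nan)
    present = ~np.isnan(mean)
    for d in range(N_DOY):
        idx = (np.arange(d - half, d + half + 1)) % N_DOY
        window = mean[idx]
        if np.isnan(window).all():
            continue
        smoothed[d] = np.nanmean(window)
    smoothed[~present] = np.nan
    return SeasonalCycle(mean=mean, smoothed=smoothed)


@dataclass
class GrowingSeasonMask:
    """Boolean per-DOY growing-season membership (index = DOY − 1)."""

    in_season: np.ndarray
    threshold_fraction: float

    def for_index(self, index: pd.DatetimeIndex) -> np.ndarray:
        return self.in_season[index.dayofyear - 1]


def growing_season_mask(
    cycle: SeasonalCycle, threshold_fraction: float = 0.25
) -> GrowingSeasonMask:
    """Days whose smoothed mean-cycle GPP exceeds a fraction of the cycle maximum.

    The default fraction is 0.25; 0.10 suits sites with bimodal seasonality or
    seasons spanning two calendar years, where the stricter threshold would cut
    the season in two.  Invariant under positive rescaling of GPP.
    """
    if np.isnan(cycle.smoothed).all():
        raise ValueError("seasonal cycle is entirely missing")
    peak = np.nanmax(cycle.smoothed)
    with np.errstate(invalid="ignore"):
        mask = cycle.smoothed > threshold_fraction * peak
    return GrowingSeasonMask(in_season=mask, threshold_fraction=threshold_fraction)


def season_segments(index: pd.DatetimeIndex, mask: GrowingSeasonMask) -> np.ndarray:
    """Label each calendar day with a growing-season segment id.

    Segments are maximal runs of consecutive in-season days; out-of-season
    days get −1.  Cross-calendar-year seasons therefore form a single
    segment, and a bimodal site contributes two segments per year.
    """
    inseason = mask.for_index(index)
    ids = np.full(len(index), -1, dtype=int)
    seg = -1
    prev = False
    for i, flag in enumerate(inseason):
        if flag and not prev:
            seg += 1
        if flag:
            ids[i] = seg
        prev = flag
    return ids


# ---------------------------------------------------------------------------
# Anomalies
# ---------------------------------------------------------------------------

ANOMALY_VARS = ("gpp", "gpp_gapfilled", "ta", "vpd", "sw_in", "wai", "ef")


@dataclass
class AnomalySeries:
    """Detrended, deseasonalized growing-season daily anomalies.

    ``data`` is indexed on the full calendar and carries ``<var>_anom``
    columns, ``doy``, ``in_season`` and ``season_id``; out-of-season rows keep
    NaN anomalies so that every consumer sees only growing-season values.
    ``gs_mean_total_gpp`` is the long-term mean of the per-season summed
    (gap-filled) GPP, the normalization base for concurrent and legacy
    effects.
    """

    data: pd.DataFrame
    cycles: dict[str, SeasonalCycle]
    slopes: dict[str, float]
    gs_mask: GrowingSeasonMask
    gs_mean_total_gpp: float
    site_id: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def season_ids(self) -> list[int]:
        ids = self.data["season_id"].to_numpy()
        return sorted(int(s) for s in np.unique(ids[ids >= 0]))

    def season_index(self, season_id: int) -> pd.DatetimeIndex:
        sel = self.data["season_id"] == season_id
        return self.data.index[sel]


def _anomalize(values: pd.Series, alpha: float, method: str) -> tuple[pd.Series, float, SeasonalCycle]:
    detrended, slope = detrend(values, alpha=alpha, method=method)
    cycle = mean_seasonal_cycle(detrended)
    anom = detrended - cycle.at_doy(detrended.index.dayofyear)
    return anom, slope, cycle


def compute_anomalies(
    frame: pd.DataFrame,
    site_id: str = "",
    gs_threshold: float = 0.25,
    trend_alpha: float = 0.05,
    trend_method: str = "ols",
) -> AnomalySeries:
    """Build the full anomaly table from a daily frame with canonical columns.

    ``frame`` must contain ``gpp`` (quality-masked), ``gpp_gapfilled``, ``ta``,
    ``vpd``, ``sw_in``, ``wai`` and ``ef``.  Each variable is detrended (see
    :func:`detrend`), deseasonalized against its raw per-DOY mean cycle, and
    restricted to the growing season derived from the smoothed gap-filled GPP
    cycle.  Anomaly cycles use the unsmoothed per-DOY mean; the smoothed cycle
    only decides season membership.
    """
    gpp_for_season = frame["gpp_gapfilled"] if "gpp_gapfilled" in frame else frame["gpp"]
    season_cycle = mean_seasonal_cycle(detrend(gpp_for_season, alpha=trend_alpha,
                                               method=trend_method)[0])
    gs = growing_season_mask(season_cycle, gs_threshold)
    inseason = gs.for_index(frame.index)
    seg_ids = season_segments(frame.index, gs)

    out = pd.DataFrame(index=frame.index)
    out["doy"] = frame.index.dayofyear
    out["in_season"] = inseason
    out["season_id"] = seg_ids
    cycles: dict[str, SeasonalCycle] = {}
    slopes: dict[str, float] = {}
    for var in ANOMALY_VARS:
        if var not in frame:
            continue
        anom, slope, cycle = _anomalize(frame[var], trend_alpha, trend_method)
        anom[~inseason] = np.nan
        out[f"{var}_anom"] = anom
        cycles[var] = cycle
        slopes[var] = slope

    gs_gpp = gpp_for_season.where(inseason)
    per_season = gs_gpp.groupby(seg_ids).sum(min_count=1)
    per_season = per_season[per_season.index >= 0]
    gs_mean_total = float(per_season.mean()) if len(per_season) else float("nan")

    return AnomalySeries(
        data=out,
        cycles=cycles,
        slopes=slopes,
        gs_mask=gs,
        gs_mean_total_gpp=gs_mean_total,
        site_id=site_id,
    )
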