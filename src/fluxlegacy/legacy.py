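"""Quantification of drought legacy effects on GPP.

Legacy effects are departures of observed GPP anomalies from the value a
response model expects given concurrent meteorology.  The response model is a
bagged regression-tree ensemble (random forest) on SW_IN, TA, VPD and WAI
anomalies plus DOY, trained on all growing-season days outside drought and
candidate-legacy windows.  The legacy window grows season by season while
weekly residuals stay significantly different from zero (Wilcoxon signed-rank
test); the final magnitude is gated day-by-day against the 5–95% band of
leave-one-year-out model residuals so that only exceedances beyond model
uncertainty count, then cumulated and normalized by the long-term mean total
growing-season GPP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .preprocessing import AnomalySeries, N_DOY
from .drought_detection import DroughtEvent

log = logging.getLogger(__name__)

PREDICTORS = ("sw_in_anom", "ta_anom", "vpd_anom", "wai_anom", "doy")
TARGET = "gpp_anom"            # quality-screened channel, used for training
RESIDUAL_TARGET = "gpp_gapfilled_anom"  # gap-filled channel, used for residuals

DEFAULT_N_TREES = 500
MIN_TRAINING_DAYS = 300


@dataclass
class ResponseModel:
    """Fitted GPP-anomaly response model with its training metadata."""

    model: RandomForestRegressor
    oob_score: float
    n_training_days: int
    predictors: tuple[str, ...] = PREDICTORS

    def predict(self, frame: pd.DataFrame) -> pd.Series:
        X = frame[list(self.predictors)]
        ok = X.notna().all(axis=1)
        out = pd.Series(np.nan, index=frame.index)
        if ok.any():
            out[ok] = self.model.predict(X[ok].to_numpy())
        return out


def _training_frame(anoms: AnomalySeries, exclude: pd.Index | None) -> pd.DataFrame:
    data = anoms.data
    frame = data[data["in_season"]]
    cols = list(PREDICTORS) + [TARGET]
    frame = frame[cols].dropna()
    if exclude is not None and len(exclude):
        frame = frame.drop(index=frame.index.intersection(exclude))
    return frame


def train_response_model(
    anoms: AnomalySeries,
    exclude: pd.Index | None = None,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    min_training_days: int = MIN_TRAINING_DAYS,
) -> ResponseModel:
    """Fit the bagged-tree response model on non-excluded growing-season days.

    ``exclude`` holds drought days plus the current candidate legacy window;
    low-quality days drop out automatically because the quality-screened GPP
    channel is missing there (they re-enter later as residual days).  The
    ensemble uses ``n_trees`` bootstrapped trees, ⌈p/3⌉ features per split,
    and out-of-bag variance explained as its skill score.  Deterministic for
    a fixed seed.
    """
    frame = _training_frame(anoms, exclude)
    if len(frame) < min_training_days:
        raise ValueError(
            f"too few training days: {len(frame)} < {min_training_days}"
        )
    max_features = int(np.ceil(len(PREDICTORS) / 3))
    model = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max_features,
        oob_score=True,
        bootstrap=True,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    model.fit(frame[list(PREDICTORS)].to_numpy(), frame[TARGET].to_numpy())
    return ResponseModel(
        model=model,
        oob_score=float(model.oob_score_),
        n_training_days=len(frame),
    )


# ---------------------------------------------------------------------------
# Residual legacy series
# ---------------------------------------------------------------------------

def daily_legacy(
    model: ResponseModel, anoms: AnomalySeries, window: pd.Index
) -> pd.Series:
    """Daily legacy = observed − expected GPP anomaly over ``window``.

    Negative values mean GPP below what concurrent meteorology explains.
    Residuals use the gap-filled GPP channel so quality-control holes do not
    puncture the legacy series.
    """
    frame = anoms.data.loc[window]
    pred = model.predict(frame)
    obs = frame[RESIDUAL_TARGET]
    return obs - pred


def weekly_average(values: pd.Series, block: int = 7) -> np.ndarray:
    """Average consecutive ``block``-day chunks; blocks restart at the first day.

    A trailing partial block is kept; all-missing blocks are dropped.
    """
    v = values.to_numpy(float)
    out = []
    for i in range(0, v.size, block):
        chunk = v[i:i + block]
        if np.isfinite(chunk).any():
            out.append(np.nanmean(chunk))
    return np.asarray(out)


def legacy_series(
    model: ResponseModel, anoms: AnomalySeries, window: pd.Index
) -> np.ndarray:
    """Weekly-averaged daily legacy values over a window (one season piece)."""
    return weekly_average(daily_legacy(model, anoms, window))


# ---------------------------------------------------------------------------
# Iterative duration search
# ---------------------------------------------------------------------------

@dataclass
class LegacyResult:
    """Outcome of the legacy quantification for one drought event."""

    event: DroughtEvent
    window: pd.Index
    duration: int
    converged: bool
    season_pvalues: list[float] = field(default_factory=list)
    oob_score: float = float("nan")
    weekly_values: np.ndarray | None = None
    cum_ungated: float = float("nan")
    cum_gated: float = float("nan")
    normalized_ungated_pct: float = float("nan")
    normalized_gated_pct: float = float("nan")
    sign: str = "none"
    discarded: bool = False


def _post_event_pieces(
    anoms: AnomalySeries, event: DroughtEvent, limit: pd.Timestamp | None = None
) -> list[pd.Index]:
    """Growing-season windows after the event: same-season remainder, then
    each subsequent whole season, optionally stopping before ``limit``."""
    pieces: list[pd.Index] = []
    remainder = anoms.season_index(event.season_id)
    remainder = remainder[remainder > event.end]
    if len(remainder):
        pieces.append(remainder)
    for sid in anoms.season_ids:
        if sid <= event.season_id:
            continue
        idx = anoms.season_index(sid)
        if limit is not None:
            idx = idx[idx < limit]
        if len(idx):
            pieces.append(idx)
    return pieces


def wilcoxon_pvalue(weekly: np.ndarray) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p-value against zero.

    Exact null for fewer than 25 non-zero weekly values, normal approximation
    with continuity correction otherwise; zero differences are dropped
    (standard Wilcoxon convention).
    """
    w = weekly[np.isfinite(weekly)]
    w = w[w != 0]
    if w.size < 1:
        return 1.0
    method = "exact" if w.size < 25 else "approx"
    try:
        return float(stats.wilcoxon(w, alternative="two-sided",
                                    correction=True, method=method).pvalue)
    except ValueError:
        return 1.0


def determine_duration(
    anoms: AnomalySeries,
    event: DroughtEvent,
    drought_days: pd.Index,
    alpha: float = 0.05,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    min_weeks: int = 4,
    next_event_start: pd.Timestamp | None = None,
    count_partial_first_season: bool = True,
) -> LegacyResult:
    """Grow the legacy window season by season until residuals lose significance.

    Each iteration trains the response model excluding drought days plus the
    current candidate window, computes weekly residuals over the newest
    season piece, and tests them against zero (Wilcoxon, two-sided).  The
    search starts with the post-drought remainder of the drought-year growing
    season and appends whole seasons while p <= ``alpha``.  Duration counts
    the consecutive significant tested pieces, the drought-year remainder
    included (set ``count_partial_first_season=False`` to count only whole
    subsequent seasons).  ``converged`` is False when the record (or
    ``next_event_start``) ends while residuals are still significant — the
    magnitude is retained but the duration is censored.  A drought-year
    remainder too short to test (< ``min_weeks`` weekly values) stays in the
    window untested; a whole season too short to test stops the search.
    """
    pieces = _post_event_pieces(anoms, event, limit=next_event_start)
    if not pieces:
        return LegacyResult(event=event, window=pd.DatetimeIndex([]),
                            duration=0, converged=True)

    window_pieces: list[pd.Index] = []
    pvalues: list[float] = []
    n_significant = 0
    converged = True
    oob = float("nan")

    for i, piece in enumerate(pieces):
        candidate = window_pieces + [piece]
        exclude = drought_days.append(candidate).unique() if candidate else drought_days
        model = train_response_model(anoms, exclude=exclude, seed=seed,
                                     n_trees=n_trees)
        oob = model.oob_score
        weekly = legacy_series(model, anoms, piece)
        if weekly.size < min_weeks:
            if i == 0:
                # untestable drought-year remainder: keep it in the window,
                # move on to the first whole season
                log.warning("season piece too short to test (%d weeks); kept "
                            "untested", weekly.size)
                window_pieces.append(piece)
                continue
            log.warning("season too short to test (%d weeks); search stopped",
                        weekly.size)
            break
        p = wilcoxon_pvalue(weekly)
        pvalues.append(p)
        if p <= alpha:
            window_pieces.append(piece)
            counts = count_partial_first_season or i > 0
            n_significant += 1 if counts else 0
            if piece is pieces[-1]:
                converged = False  # record ended while still significant
        else:
            break

    window = (
        window_pieces[0].append(window_pieces[1:]).unique().sort_values()
        if window_pieces else pd.DatetimeIndex([])
    )
    return LegacyResult(
        event=event, window=window, duration=n_significant,
        converged=converged, season_pvalues=pvalues, oob_score=oob,
    )


# ---------------------------------------------------------------------------
# Leave-one-year-out uncertainty and gating
# ---------------------------------------------------------------------------

@dataclass
class UncertaintyDistribution:
    """Per-DOY leave-one-out residual distributions with their 5–95% band."""

    q05: np.ndarray  # length 366, index = DOY − 1
    q95: np.ndarray
    n_iterations: int

    def band(self, doy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = np.asarray(doy, int) - 1
        return self.q05[d], self.q95[d]


def loo_uncertainty(
    anoms: AnomalySeries,
    legacy_window: pd.Index,
    drought_days: pd.Index,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    neighbor_halfwidth: int = 3,
) -> tuple[UncertaintyDistribution, pd.Series]:
    """Leave-one-year-out residual distributions and median window predictions.

    Every non-legacy year is held out in turn; the model trained on the
    remaining years predicts (a) the held-out year, whose residuals
    (observed − predicted) pool into a per-DOY uncertainty distribution, and
    (b) the legacy window, whose per-day median across iterations is the
    expected GPP anomaly used in the gate.  DOYs with an empty pool borrow
    from a ±``neighbor_halfwidth``-day neighborhood (logged).
    """
    exclude_always = drought_days.append([legacy_window]).unique()
    data = anoms.data
    inseason_idx = data.index[data["in_season"]]
    candidate_idx = inseason_idx.difference(exclude_always)
    years = sorted({ts.year for ts in candidate_idx})
    if len(years) < 3:
        raise ValueError(f"need >= 3 non-legacy years, have {len(years)}")

    pools: list[list[float]] = [[] for _ in range(N_DOY)]
    window_preds: list[pd.Series] = []
    wframe = data.loc[legacy_window]

    for k, year in enumerate(years):
        held = candidate_idx[candidate_idx.year == year]
        exclude = exclude_always.append([held]).unique()
        model = train_response_model(
            anoms, exclude=exclude, seed=seed + 1000 * (k + 1), n_trees=n_trees
        )
        hframe = data.loc[held]
        resid = (hframe[RESIDUAL_TARGET] - model.predict(hframe)).dropna()
        for ts, r in resid.items():
            pools[ts.dayofyear - 1].append(float(r))
        window_preds.append(model.predict(wframe))

    q05 = np.full(N_DOY, np.nan)
    q95 = np.full(N_DOY, np.nan)
    borrowed = 0
    for d in range(N_DOY):
        sample = pools[d]
        if not sample:
            for off in range(1, neighbor_halfwidth + 1):
                sample = pools[(d - off) % N_DOY] + pools[(d + off) % N_DOY]
                if sample:
                    borrowed += 1
                    break
        if sample:
            q05[d] = np.percentile(sample, 5)
            q95[d] = np.percentile(sample, 95)
    if borrowed:
        log.debug("borrowed neighbor pools for %d DOYs", borrowed)

    median_pred = pd.concat(window_preds, axis=1).median(axis=1)
    return UncertaintyDistribution(q05=q05, q95=q95, n_iterations=len(years)), median_pred


def gate_legacy(
    obs: pd.Series, median_pred: pd.Series, unc: UncertaintyDistribution
) -> pd.Series:
    """Keep only the part of observed − expected outside the residual band.

    With d_t = observed − median expected and [q05, q95] the per-DOY 5–95%
    band of leave-one-out residuals: differences inside the band are model
    uncertainty and map to 0; exceedances keep only the part beyond the band
    (d − q05 below, d − q95 above).  Piecewise linear, continuous, monotone
    in d_t.
    """
    d = (obs - median_pred).to_numpy(float)
    q05, q95 = unc.band(obs.index.dayofyear)
    out = np.zeros(d.size)
    below = d < q05
    above = d > q95
    out[below] = d[below] - q05[below]
    out[above] = d[above] - q95[above]
    out[~np.isfinite(d)] = np.nan
    return pd.Series(out, index=obs.index)


def cumulative_legacy(gated: pd.Series, gs_mean_total_gpp: float) -> tuple[float, float]:
    """Sum gated daily legacy (gC m⁻²) and normalize to % of mean seasonal GPP."""
    cum = float(np.nansum(gated.to_numpy(float)))
    return cum, 100.0 * cum / gs_mean_total_gpp


# ---------------------------------------------------------------------------
# Per-event orchestration
# ---------------------------------------------------------------------------

def quantify_event(
    anoms: AnomalySeries,
    event: DroughtEvent,
    drought_days: pd.Index,
    alpha: float = 0.05,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    next_event_start: pd.Timestamp | None = None,
    count_partial_first_season: bool = True,
) -> LegacyResult:
    """Full legacy quantification: duration search, LOO gating, cumulation."""
    result = determine_duration(
        anoms, event, drought_days, alpha=alpha, seed=seed, n_trees=n_trees,
        next_event_start=next_event_start,
        count_partial_first_season=count_partial_first_season,
    )
    if len(result.window) == 0:
        result.cum_ungated = result.cum_gated = 0.0
        result.normalized_ungated_pct = result.normalized_gated_pct = 0.0
        return result

    unc, median_pred = loo_uncertainty(
        anoms, result.window, drought_days, seed=seed, n_trees=n_trees
    )
    obs = anoms.data.loc[result.window, RESIDUAL_TARGET]
    d = obs - median_pred
    gated = gate_legacy(obs, median_pred, unc)

    result.weekly_values = weekly_average(d)
    result.cum_ungated, result.normalized_ungated_pct = cumulative_legacy(
        d, anoms.gs_mean_total_gpp
    )
    result.cum_gated, result.normalized_gated_pct = cumulative_legacy(
        gated, anoms.gs_mean_total_gpp
    )
    if result.duration >= 1 and result.cum_gated != 0.0:
        result.sign = "negative" if result.cum_gated < 0 else "positive"
    return result
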