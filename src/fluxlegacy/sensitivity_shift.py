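"""Climate-sensitivity shifts between legacy and non-legacy periods.

Tests whether the GPP-anomaly response to each climatic predictor changes
after drought: two response models are fitted on the legacy window and on an
equally sized subsample of non-legacy days, per-observation additive
attributions are computed for each predictor, attribution-vs-predictor
response curves are smoothed with LOESS (span 1) inside the predictors'
common value range, and the share of the range where the two 95% confidence
bands intersect is the overlap percentage.  Low overlap indicates a shifted
sensitivity.

Attributions are tree-path-dependent: descending each decision tree, the
change in node mean value at every split is credited to the split feature, so
per-observation contributions respect the empirical feature dependence
encoded in the tree structure and sum exactly to prediction − base value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .legacy import AnomalySeries, ResponseModel, train_response_model, PREDICTORS

log = logging.getLogger(__name__)

#: predictors compared between periods; DOY is a clock, not climate
SHIFT_PREDICTORS = ("sw_in_anom", "ta_anom", "vpd_anom", "wai_anom")

MIN_LEGACY_DAYS = 30
MIN_COMMON_POINTS = 20


def fit_period_models(
    anoms: AnomalySeries,
    legacy_window: pd.Index,
    drought_days: pd.Index,
    seed: int = 0,
    n_trees: int = 500,
) -> tuple[ResponseModel, ResponseModel, pd.Index, pd.Index]:
    """Fit one response model per period on size-matched training sets.

    Non-legacy days (growing season, outside drought and legacy windows) are
    subsampled without replacement down to the legacy sample size so neither
    curve benefits from more data.  Returns both models plus the day indices
    actually used (legacy, non-legacy).
    """
    data = anoms.data
    frame = data[data["in_season"]][list(PREDICTORS) + ["gpp_gapfilled_anom"]].dropna()
    legacy_idx = frame.index.intersection(legacy_window)
    if len(legacy_idx) < MIN_LEGACY_DAYS:
        raise ValueError(
            f"legacy window too short for a sensitivity comparison "
            f"({len(legacy_idx)} days < {MIN_LEGACY_DAYS})"
        )
    nonlegacy_idx = frame.index.difference(legacy_window).difference(drought_days)
    rng = np.random.default_rng(seed)
    if len(nonlegacy_idx) > len(legacy_idx):
        keep = rng.choice(len(nonlegacy_idx), size=len(legacy_idx), replace=False)
        nonlegacy_idx = nonlegacy_idx[np.sort(keep)]

    all_but_legacy = frame.index.difference(legacy_idx)
    all_but_nonlegacy = frame.index.difference(nonlegacy_idx)
    m_legacy = train_response_model(
        anoms, exclude=all_but_legacy, seed=seed, n_trees=n_trees,
        min_training_days=MIN_LEGACY_DAYS,
    )
    m_nonlegacy = train_response_model(
        anoms, exclude=all_but_nonlegacy, seed=seed, n_trees=n_trees,
        min_training_days=MIN_LEGACY_DAYS,
    )
    return m_legacy, m_nonlegacy, legacy_idx, nonlegacy_idx


# ---------------------------------------------------------------------------
# Tree-path additive attributions
# ---------------------------------------------------------------------------

def attribution_values(model: ResponseModel, frame: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-observation, per-predictor additive attributions and the base value.

    For each tree the prediction decomposes along the decision path: every
    split changes the running node mean, and that change is credited to the
    split feature.  Averaged over the ensemble this yields attributions with
    exact local accuracy: base + Σ_features attribution = model prediction.
    """
    X = frame[list(model.predictors)].to_numpy()
    n, p = X.shape
    total = np.zeros((n, p))
    base = 0.0
    for est in model.model.estimators_:
        tree = est.tree_
        feature = tree.feature
        values = tree.value.reshape(-1)
        # per-node contribution credited to the parent's split feature
        contrib = np.zeros((tree.node_count, p))
        left, right = tree.children_left, tree.children_right
        for node in range(tree.node_count):
            for child in (left[node], right[node]):
                if child != -1:
                    contrib[child, feature[node]] = values[child] - values[node]
        paths = est.decision_path(X)  # sparse (n, node_count)
        total += paths @ contrib
        base += values[0]
    n_trees = len(model.model.estimators_)
    attr = pd.DataFrame(total / n_trees, index=frame.index,
                        columns=list(model.predictors))
    return attr, base / n_trees


# ---------------------------------------------------------------------------
# LOESS response curves and band overlap
# ---------------------------------------------------------------------------

def loess_fit(
    x: np.ndarray, y: np.ndarray, grid: np.ndarray, span: float = 1.0,
    ci_level: float = 0.95,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Locally weighted linear smoother with pointwise confidence bands.

    At each grid point the ``span`` fraction of nearest observations gets
    tricube weights and a weighted straight line is fitted; the fitted value
    is a linear functional l(x₀)ᵀy, so its pointwise variance is
    σ̂²·‖l(x₀)‖² with σ̂² estimated from the smoother's residuals.  Returns
    (fit, lower, upper).
    """
    order = np.argsort(x)
    x, y = np.asarray(x, float)[order], np.asarray(y, float)[order]
    n = x.size
    k = max(3, int(np.ceil(span * n)))
    fit = np.empty(grid.size)
    lnorm2 = np.empty(grid.size)
    hat_diag_sum = 0.0

    # residual variance from the smoother evaluated at the data points
    resid = np.empty(n)

    def _weights(x0: float) -> np.ndarray:
        d = np.abs(x - x0)
        dmax = np.partition(d, k - 1)[k - 1]
        if dmax == 0:
            w = (d == 0).astype(float)
        else:
            w = np.clip(1 - (d / dmax) ** 3, 0, None) ** 3
        return w

    def _lvec(x0: float) -> np.ndarray:
        w = _weights(x0)
        sw = w.sum()
        xm = (w * x).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        l = w / sw
        if sxx > 0:
            l = l + w * (x - xm) * (x0 - xm) / sxx
        return l

    for i in range(n):
        l = _lvec(x[i])
        resid[i] = y[i] - l @ y
        hat_diag_sum += l[i]
    dof = max(1.0, n - hat_diag_sum)
    sigma2 = float((resid ** 2).sum() / dof)

    for j, x0 in enumerate(grid):
        l = _lvec(x0)
        fit[j] = l @ y
        lnorm2[j] = float(l @ l)
    half = stats.norm.ppf(0.5 + ci_level / 2) * np.sqrt(sigma2 * lnorm2)
    return fit, fit - half, fit + half


@dataclass
class ShiftResult:
    """Per-predictor overlap of legacy vs non-legacy response curves."""

    predictor: str
    common_range: tuple[float, float]
    overlap_pct: float
    grid: np.ndarray
    bands_legacy: tuple[np.ndarray, np.ndarray]
    bands_nonlegacy: tuple[np.ndarray, np.ndarray]


def response_overlap(
    attr_legacy: pd.Series,
    x_legacy: pd.Series,
    attr_nonlegacy: pd.Series,
    x_nonlegacy: pd.Series,
    n_grid: int = 100,
    span: float = 1.0,
) -> ShiftResult | None:
    """Overlap percentage of the two attribution response curves.

    Both periods are restricted to the common predictor range; LOESS(span=1)
    curves with pointwise 95% bands are compared on an even ``n_grid`` grid,
    and the overlap is the share of grid points where the bands intersect.
    Symmetric in period order.  Returns None (logged) when the common range
    is empty or either period has too few points inside it.
    """
    lo = max(np.nanmin(x_legacy), np.nanmin(x_nonlegacy))
    hi = min(np.nanmax(x_legacy), np.nanmax(x_nonlegacy))
    if not hi > lo:
        log.warning("empty common range for %s", x_legacy.name)
        return None

    def _clip(a: pd.Series, x: pd.Series):
        sel = (x >= lo) & (x <= hi) & a.notna() & x.notna()
        return a[sel].to_numpy(), x[sel].to_numpy()

    a1, x1 = _clip(attr_legacy, x_legacy)
    a2, x2 = _clip(attr_nonlegacy, x_nonlegacy)
    if len(a1) < MIN_COMMON_POINTS or len(a2) < MIN_COMMON_POINTS:
        log.warning("too few points in common range (%d, %d)", len(a1), len(a2))
        return None

    grid = np.linspace(lo, hi, n_grid)
    f1, lo1, hi1 = loess_fit(x1, a1, grid, span=span)
    f2, lo2, hi2 = loess_fit(x2, a2, grid, span=span)
    intersect = (lo1 <= hi2) & (lo2 <= hi1)
    return ShiftResult(
        predictor=str(x_legacy.name),
        common_range=(float(lo), float(hi)),
        overlap_pct=100.0 * float(np.mean(intersect)),
        grid=grid,
        bands_legacy=(lo1, hi1),
        bands_nonlegacy=(lo2, hi2),
    )


def sensitivity_shift(
    anoms: AnomalySeries,
    legacy_window: pd.Index,
    drought_days: pd.Index,
    seed: int = 0,
    n_trees: int = 500,
    predictors: tuple[str, ...] = SHIFT_PREDICTORS,
) -> dict[str, ShiftResult | None]:
    """Full per-site comparison: fit period models, attribute, measure overlap."""
    m_leg, m_non, idx_leg, idx_non = fit_period_models(
        anoms, legacy_window, drought_days, seed=seed, n_trees=n_trees
    )
    data = anoms.data
    frame_leg = data.loc[idx_leg]
    frame_non = data.loc[idx_non]
    attr_leg, _ = attribution_values(m_leg, frame_leg)
    attr_non, _ = attribution_values(m_non, frame_non)
    out: dict[str, ShiftResult | None] = {}
    for var in predictors:
        out[var] = response_overlap(
            attr_leg[var], frame_leg[var], attr_non[var], frame_non[var]
        )
    return out
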