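"""Bucket water balance: water availability index (WAI) from observed P and ET.

The soil water store is a single bucket whose capacity equals the maximum
cumulative water deficit (CWD) experienced over the record — the historically
driest excursion defines how much water the profile can hold for the
vegetation.  ET comes from observed latent heat via the temperature-dependent
heat of vaporization.  The bucket is spun up by cycling the first calendar
year five times before the actual pass over the record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86400.0


def latent_heat_of_vaporization(ta_c) -> np.ndarray:
    """λ(T) in J kg⁻¹: (2.501 − 0.002361·T)·10⁶, T in °C."""
    return (2.501 - 0.002361 * np.asarray(ta_c, float)) * 1.0e6


def et_from_le(le, ta=None, lam: float | None = None) -> np.ndarray:
    """Convert latent heat flux (W m⁻²) to ET (mm d⁻¹) using λ(T).

    1 W m⁻² sustained over a day is 86 400 J m⁻²; dividing by λ gives kg m⁻²,
    i.e. mm of water.  Missing LE or TA yields missing ET.  A constant λ
    (J kg⁻¹) can be forced via ``lam`` for strict comparability across sites.
    """
    le = np.asarray(le, float)
    if lam is None:
        if ta is None:
            raise ValueError("either ta or a constant lam is required")
        lam = latent_heat_of_vaporization(ta)
    return le * SECONDS_PER_DAY / lam


def max_cumulative_water_deficit(p, et) -> float:
    """Maximum running water deficit: D_t = max(0, D_{t−1} + ET_t − P_t).

    Missing days contribute zero net flux.  The result (mm) is used as the
    bucket capacity; an always-wet record yields 0, which is a degenerate
    bucket and fatal downstream.
    """
    p = np.nan_to_num(np.asarray(p, float))
    et = np.nan_to_num(np.asarray(et, float))
    if p.size == 0 or et.size == 0:
        raise ValueError("empty precipitation/ET series")
    deficit = 0.0
    worst = 0.0
    for net in et - p:
        deficit = max(0.0, deficit + net)
        worst = max(worst, deficit)
    return float(worst)


@dataclass
class WaterBalanceSeries:
    """Daily WAI (mm) with the capacity and spin-up state that produced it."""

    wai: pd.Series
    wai_max: float
    wai_0: float

    def __post_init__(self) -> None:
        vals = self.wai.to_numpy(float)
        if np.nanmin(vals) < -1e-9 or np.nanmax(vals) > self.wai_max + 1e-9:
            raise ValueError("WAI left the [0, WAI_max] envelope")


def _iterate(p: np.ndarray, et: np.ndarray, wai_max: float, w0: float) -> np.ndarray:
    out = np.empty(p.size)
    w = w0
    for i in range(p.size):
        w = min(wai_max, max(0.0, w + p[i] - et[i]))
        out[i] = w
    return out


def run_bucket(
    p: pd.Series,
    et: pd.Series,
    wai_max: float,
    spinup_passes: int = 5,
    spinup_start: float | None = None,
) -> WaterBalanceSeries:
    """Run the bucket recursion WAI_t = min(WAI_max, max(0, WAI_{t−1} + P − ET)).

    Spin-up cycles the first calendar year ``spinup_passes`` times starting
    from a full bucket (configurable via ``spinup_start``); the final spin-up
    state becomes WAI_0.  The lower clamp at 0 reflects that the store cannot
    go negative — with capacity set to the maximum CWD it binds exactly at the
    historically driest point.  Missing P or ET days carry the store (zero
    flux).
    """
    if wai_max <= 0:
        raise ValueError("bucket capacity must be positive (wet-record CWD of 0 "
                         "cannot define a water availability index)")
    if not p.index.equals(et.index):
        raise ValueError("P and ET must share an index")
    pv = np.nan_to_num(p.to_numpy(float))
    ev = np.nan_to_num(et.to_numpy(float))

    first_year = p.index.year == p.index.year[0]
    w = wai_max if spinup_start is None else float(spinup_start)
    for _ in range(spinup_passes):
        trace = _iterate(pv[first_year], ev[first_year], wai_max, w)
        w = trace[-1]
    wai_0 = w
    values = _iterate(pv, ev, wai_max, wai_0)
    return WaterBalanceSeries(
        wai=pd.Series(values, index=p.index, name="wai"),
        wai_max=float(wai_max),
        wai_0=float(wai_0),
    )


def water_availability_index(
    p: pd.Series, le: pd.Series, ta: pd.Series, wai_max: float | None = None,
    lam: float | None = None, **kwargs,
) -> WaterBalanceSeries:
    """Convenience wrapper: ET from LE, capacity from max CWD, then the bucket."""
    et = pd.Series(et_from_le(le, ta, lam=lam), index=le.index)
    if wai_max is None:
        wai_max = max_cumulative_water_deficit(p.to_numpy(), et.to_numpy())
    return run_bucket(p, et, wai_max, **kwargs)
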