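"""Reading, validation, and record-level screening of daily flux-tower CSV files.

The on-disk dialect is the FLUXNET FULLSET daily product: comma-separated,
``TIMESTAMP`` in YYYYMMDD, ``-9999`` as the missing-value sentinel, and
per-variable quality-control columns giving the daily fraction of measured or
good-quality gap-filled half-hours.  AmeriFlux/ICOS/OzFlux naming differences
are handled declaratively through a column map rather than in code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING_SENTINEL = -9999.0

#: canonical internal variable -> default FLUXNET FULLSET daily column
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "timestamp": "TIMESTAMP",
    "gpp": "GPP_NT_VUT_REF",
    "le": "LE_F_MDS",
    "h": "H_F_MDS",
    "ta": "TA_F",
    "vpd": "VPD_F",
    "sw_in": "SW_IN_F",
    "netrad": "NETRAD",
    "precip": "P_F",
    "qc_gpp": "NEE_VUT_REF_QC",
    "qc_le": "LE_F_MDS_QC",
    "qc_h": "H_F_MDS_QC",
    "qc_ta": "TA_F_QC",
    "qc_vpd": "VPD_F_QC",
    "qc_sw_in": "SW_IN_F_QC",
}

#: variables that must be present; QC columns are optional (assumed 1.0 if absent)
REQUIRED_VARS = ("gpp", "le", "h", "ta", "vpd", "sw_in", "netrad", "precip")
QC_VARS = ("qc_gpp", "qc_le", "qc_h", "qc_ta", "qc_vpd", "qc_sw_in")

#: turbulent-flux variables masked by the quality filter (paired with their QC)
FLUX_QC_PAIRS = (("gpp", "qc_gpp"), ("le", "qc_le"), ("h", "qc_h"))


class FluxDataError(ValueError):
    """Fatal problem with an input flux record (missing column, bad calendar...)."""


@dataclass
class SiteTimeSeries:
    """Daily observed fluxes and meteorology for one site.

    ``data`` is indexed by a strictly increasing, gap-free daily
    :class:`~pandas.DatetimeIndex` and carries the canonical columns
    ``gpp, le, h, ta, vpd, sw_in, netrad, precip`` plus ``qc_*`` fractions in
    [0, 1].  After :func:`apply_quality_filter` an extra ``gpp_gapfilled``
    column preserves the unmasked (gap-filled) GPP for concurrent-effect use.
    Years removed by :func:`screen_years` stay on the calendar with all data
    set to missing, so the daily-step invariant survives screening.
    """

    site_id: str
    data: pd.DataFrame
    removed_years: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise FluxDataError("index must be a DatetimeIndex")
        if len(idx) > 1:
            deltas = np.diff(idx.values).astype("timedelta64[D]").astype(int)
            bad = np.nonzero(deltas != 1)[0]
            if bad.size:
                raise FluxDataError(
                    f"calendar not daily/contiguous at {idx[bad[0]].date()} -> "
                    f"{idx[bad[0] + 1].date()}"
                )
        for qc in QC_VARS:
            if qc in self.data:
                vals = self.data[qc].to_numpy(float)
                ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
                if not ok.all():
                    raise FluxDataError(f"{qc} outside [0, 1]")
        if "precip" in self.data:
            p = self.data["precip"].to_numpy(float)
            if np.nanmin(p, initial=0.0) < 0:
                raise FluxDataError("negative precipitation")

    @property
    def years(self) -> list[int]:
        """Calendar years with any non-missing LE (screened years excluded)."""
        le = self.data["le"]
        valid = le.notna().groupby(le.index.year).any()
        return [int(y) for y in valid.index[valid]]

    @property
    def n_years(self) -> int:
        return len(self.years)


def read_daily_flux(
    path,
    site_id: str | None = None,
    column_map: dict[str, str] | None = None,
) -> SiteTimeSeries:
    """Read a FLUXNET-dialect daily CSV into a validated :class:`SiteTimeSeries`.

    ``column_map`` overrides entries of :data:`DEFAULT_COLUMN_MAP`.  ``-9999``
    sentinels become missing.  A missing required column or a non-daily /
    gapped calendar raises :class:`FluxDataError`.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, float_precision="round_trip")

    tcol = cmap["timestamp"]
    if tcol not in raw.columns:
        raise FluxDataError(f"missing required column {tcol!r}")
    missing = [cmap[v] for v in REQUIRED_VARS if cmap[v] not in raw.columns]
    if missing:
        raise FluxDataError(f"missing required column(s): {', '.join(missing)}")

    dates = pd.to_datetime(raw[tcol].astype(str), format="%Y%m%d")
    out = pd.DataFrame(index=pd.DatetimeIndex(dates, name="date"))
    for var in REQUIRED_VARS:
        out[var] = raw[cmap[var]].to_numpy(float)
    for qc in QC_VARS:
        col = cmap.get(qc)
        out[qc] = raw[col].to_numpy(float) if col in raw.columns else 1.0
    out = out.mask(out <= MISSING_SENTINEL + 0.5)

    if site_id is None:
        site_id = str(path)
    return SiteTimeSeries(site_id=site_id, data=out)


def write_daily_flux(series: SiteTimeSeries, path, column_map: dict[str, str] | None = None) -> None:
    """Write a SiteTimeSeries back to the FLUXNET CSV dialect (−9999 sentinel)."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    out = pd.DataFrame()
    out[cmap["timestamp"]] = series.data.index.strftime("%Y%m%d")
    for var in REQUIRED_VARS + QC_VARS:
        if var in series.data:
            out[cmap[var]] = series.data[var].fillna(MISSING_SENTINEL).to_numpy()
    out.to_csv(path, index=False)  # full repr precision: round-trip exact


def apply_quality_filter(series: SiteTimeSeries, min_qc: float = 0.7) -> SiteTimeSeries:
    """Mask turbulent fluxes on days whose QC fraction falls below ``min_qc``.

    A day is retained when at least ``min_qc`` of its half-hours were measured
    or good-quality gap-filled (default 0.7, i.e. QC >= 0.7 kept).  The
    gap-filled GPP is preserved unmasked in ``gpp_gapfilled`` because gaps
    inside drought windows would bias cumulative concurrent effects.
    Idempotent.
    """
    if not 0.0 <= min_qc <= 1.0:
        raise ValueError("min_qc must be in [0, 1]")
    data = series.data.copy()
    if "gpp_gapfilled" not in data:
        data["gpp_gapfilled"] = data["gpp"]
    for var, qc in FLUX_QC_PAIRS:
        bad = data[qc] < min_qc
        data.loc[bad, var] = np.nan
    return replace(series, data=data)


def _max_missing_run(mask: np.ndarray) -> int:
    """Length of the longest True run in a boolean array."""
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def screen_years(
    series: SiteTimeSeries, max_le_gap: int = 60, min_years: int = 7
) -> SiteTimeSeries:
    """Drop calendar years with a long run of missing LE.

    A year is removed in full when it contains a missing-LE run of at least
    ``max_le_gap`` consecutive days (such seasons would corrupt the bucket
    water balance).  Removed years stay on the calendar as all-missing rows.
    Fewer than ``min_years`` surviving years is fatal: shorter records do not
    support a stable response model.
    """
    if max_le_gap <= 0:
        raise ValueError("max_le_gap must be positive")
    data = series.data.copy()
    le_missing = data["le"].isna().to_numpy()
    years = data.index.year
    removed = list(series.removed_years)
    for year in np.unique(years):
        sel = years == year
        if _max_missing_run(le_missing[sel]) >= max_le_gap:
            removed.append(int(year))
            value_cols = [c for c in data.columns if not c.startswith("qc_")]
            data.loc[sel, value_cols] = np.nan
    remaining = [int(y) for y in np.unique(years) if int(y) not in removed]
    if len(remaining) < min_years:
        raise FluxDataError(
            f"insufficient record: {len(remaining)} years remain after screening "
            f"(need >= {min_years})"
        )
    return replace(series, data=data, removed_years=sorted(set(removed)))
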