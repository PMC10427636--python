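"""Drought detection: growing season, cell selection, peaks, durations.

Severe-drought cells are those whose 40-year record minimum of yearly
(monthly-resolution) soil-moisture minima falls inside the study period;
within each selected cell the drought peak is the in-season minimum of the
8-daily soil moisture (or of its anomaly, for the anomaly variant).
Trajectories are the 24 8-daily steps from 12 before to 11 after the peak,
i.e. three months on either side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .cubes import CELL, TIME, months_of, years_of

log = logging.getLogger(__name__)

TRAJ_PRE = 12  # steps before the peak in the display window
TRAJ_POST = 11  # steps after the peak
TRAJ_LEN = TRAJ_PRE + TRAJ_POST + 1  # 24
MIN_VALID_TRAJ = 20

TA_THRESHOLD_K = 278.15  # 5 degC
SIF_CLIM_THRESHOLD = 0.2  # mW m-2 sr-1 nm-1


@dataclass
class DroughtEvent:
    cell: int
    peak_step: int
    peak_time: pd.Timestamp
    dev_duration: int
    recov_duration: int
    dev_censored: bool
    recov_censored: bool
    severe: bool
    variant: str


def growing_season_mask(ta: xr.DataArray, sif_clim: xr.DataArray) -> xr.DataArray:
    """Step in season iff Ta > 5 degC and the month's SIF climatology > 0.2.

    ``sif_clim`` is the (cell x 12) monthly climatology of raw SIF.  Missing
    temperature or climatology puts the step out of season.
    """
    months = months_of(ta)
    clim_at_t = sif_clim.values[:, months - 1]
    ta_v = ta.values
    mask = (
        np.isfinite(ta_v)
        & (ta_v > TA_THRESHOLD_K)
        & np.isfinite(clim_at_t)
        & (clim_at_t > SIF_CLIM_THRESHOLD)
    )
    out = ta.copy(data=mask)
    out.name = "growing_season"
    out.attrs = {}
    return out


def select_drought_cells(
    sm_monthly: xr.DataArray,
    study_years,
    monthly_season: xr.DataArray | None = None,
    min_valid_years: int = 30,
) -> pd.DataFrame:
    """Rank yearly soil-moisture minima; select cells with the record minimum
    inside the study window.

    Returns a per-cell table with ``selected``, the year of the strongest
    (rank-1) and second-strongest yearly minimum, and ``second_in_study``
    for the multiple-drought robustness subset.  Rank ties are broken in
    favour of the latest year (inclusive reading of the study window).
    """
    study_years = set(int(y) for y in study_years)
    years = years_of(sm_monthly)
    vals = sm_monthly.values
    if monthly_season is not None:
        vals = np.where(monthly_season.values, vals, np.nan)
    uyears = np.unique(years)
    yearly_min = np.full((vals.shape[0], uyears.size), np.nan)
    for j, y in enumerate(uyears):
        sel = years == y
        sub = vals[:, sel]
        any_valid = np.isfinite(sub).any(axis=1)
        mins = np.nanmin(np.where(np.isfinite(sub), sub, np.inf), axis=1)
        yearly_min[:, j] = np.where(any_valid, mins, np.nan)
    rows = []
    for i in range(vals.shape[0]):
        ym = yearly_min[i]
        valid = np.isfinite(ym)
        if valid.sum() < min_valid_years:
            log.info("select_drought_cells: cell %d has <%d valid years", i, min_valid_years)
            rows.append((i, False, np.nan, np.nan, False))
            continue
        order = np.argsort(ym[valid], kind="stable")
        yrs_valid = uyears[valid]
        m = ym[valid]
        # tie-break: among equal minima, the latest year wins
        min_val = m[order[0]]
        tied = np.where(np.isclose(m, min_val))[0]
        first_year = int(yrs_valid[tied].max())
        rest = [k for k in order if int(yrs_valid[k]) != first_year]
        second_year = int(yrs_valid[rest[0]]) if rest else np.nan
        selected = first_year in study_years
        second_in_study = bool(rest) and second_year in study_years
        rows.append((i, bool(selected), first_year, second_year, bool(second_in_study)))
    return pd.DataFrame(
        rows,
        columns=["cell", "selected", "min_year", "second_min_year", "second_in_study"],
    ).set_index("cell")


def find_peak(
    sm_8daily: xr.DataArray,
    growing_mask: xr.DataArray,
    cells=None,
    variant: str = "absolute",
    anomalies: xr.DataArray | None = None,
) -> pd.Series:
    """Peak step (index on the 8-daily axis) per cell: in-season argmin of
    soil moisture, or of its anomaly for the anomaly variant; ties take the
    earliest step.  Cells with no valid in-season value get no event."""
    if variant == "anomaly":
        if anomalies is None:
            raise ValueError("anomaly variant requires an anomaly cube")
        target = anomalies.values
    elif variant == "absolute":
        target = sm_8daily.values
    else:
        raise ValueError(f"unknown variant: {variant}")
    masked = np.where(growing_mask.values, target, np.nan)
    idx = sm_8daily[CELL].values if cells is None else np.asarray(cells)
    out = {}
    for c in idx:
        i = int(np.where(sm_8daily[CELL].values == c)[0][0])
        row = masked[i]
        if not np.isfinite(row).any():
            continue
        out[int(c)] = int(np.nanargmin(row))  # nanargmin returns the first min
    return pd.Series(out, name="peak_step", dtype=int)


def durations(anom: np.ndarray, peak_step: int) -> tuple[int, int, bool, bool]:
    """Development/recovery durations by the stopping rule: count consecutive
    steps with anomaly < 0 walking backward (including the peak) and forward
    from the peak, stopping at the first >= 0 anomaly.  A missing value
    during the walk stops it and flags the side as censored; hitting the
    record edge also censors."""
    anom = np.asarray(anom, dtype=float)
    n = anom.size
    dev = 0
    dev_cens = False
    j = peak_step
    while j >= 0:
        v = anom[j]
        if not np.isfinite(v):
            dev_cens = True
            break
        if v >= 0:
            break
        dev += 1
        j -= 1
    else:
        dev_cens = True
    recov = 0
    recov_cens = False
    j = peak_step + 1
    while j < n:
        v = anom[j]
        if not np.isfinite(v):
            recov_cens = True
            break
        if v >= 0:
            break
        recov += 1
        j += 1
    else:
        recov_cens = True
    return dev, recov, dev_cens, recov_cens


def severity_filter(
    sm_at_peak: float, seasonal_mean: float, seasonal_sd: float, z: float = -1.5
) -> bool:
    """True iff soil moisture at the peak is below mean + z * SD of the
    40-year record for the peak's calendar month."""
    if not np.isfinite(seasonal_sd) or seasonal_sd <= 0:
        log.info("severity_filter: zero/undefined seasonal SD")
        return False
    return bool(sm_at_peak < seasonal_mean + z * seasonal_sd)


def detect_events(
    sm_8daily: xr.DataArray,
    sm_anom: xr.DataArray,
    growing_mask: xr.DataArray,
    selection: pd.DataFrame,
    sm_monthly: xr.DataArray,
    variant: str = "absolute",
) -> pd.DataFrame:
    """Assemble the per-cell drought event table for the selected cells."""
    cells = selection.index[selection["selected"]].values
    peaks = find_peak(sm_8daily, growing_mask, cells=cells, variant=variant,
                      anomalies=sm_anom)
    months = months_of(sm_monthly)
    time8 = pd.DatetimeIndex(sm_8daily[TIME].values)
    cell_ids = sm_8daily[CELL].values
    rows = []
    for c, p in peaks.items():
        i = int(np.where(cell_ids == c)[0][0])
        dev, recov, dc, rc = durations(sm_anom.values[i], p)
        peak_month = time8[p].month
        sel = months == peak_month
        mrow = sm_monthly.values[i, sel]
        severe = severity_filter(
            sm_8daily.values[i, p], np.nanmean(mrow), np.nanstd(mrow, ddof=1)
        )
        rows.append(
            DroughtEvent(int(c), int(p), time8[p], dev, recov, dc, rc, severe, variant)
        )
    df = pd.DataFrame([vars(e) for e in rows])
    return df.set_index("cell") if len(df) else df


def extract_trajectory(
    anom: xr.DataArray, peaks: pd.Series, pre: int = TRAJ_PRE, post: int = TRAJ_POST
) -> xr.Dataset:
    """Anomaly window [peak-pre, peak+post] per cell, missing-padded at the
    record edges, with the per-cell count of valid steps."""
    cell_ids = anom[CELL].values
    vals = anom.values
    n_t = vals.shape[1]
    length = pre + post + 1
    out = np.full((len(peaks), length), np.nan)
    for k, (c, p) in enumerate(peaks.items()):
        i = int(np.where(cell_ids == c)[0][0])
        lo, hi = p - pre, p + post + 1
        src_lo, src_hi = max(lo, 0), min(hi, n_t)
        out[k, src_lo - lo : src_lo - lo + (src_hi - src_lo)] = vals[i, src_lo:src_hi]
    rel = np.arange(-pre, post + 1)
    traj = xr.DataArray(
        out, dims=(CELL, "rel_step"),
        coords={CELL: np.asarray(list(peaks.index)), "rel_step": rel},
        name="trajectory",
    )
    valid = xr.DataArray(
        np.isfinite(out).sum(axis=1), dims=(CELL,),
        coords={CELL: traj[CELL]}, name="valid_count",
    )
    return xr.Dataset({"trajectory": traj, "valid_count": valid})
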