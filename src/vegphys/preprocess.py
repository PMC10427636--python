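"""Temporal aggregation, anomaly extraction and spatial masking.

All observation and meteorological series are brought to a common 8-daily
grid by a 16-day moving-window mean, split into a monthly mean seasonal
cycle, a locally weighted (LOWESS) trend of the deseasonalized residual,
and the remaining anomaly.  Analyses downstream work exclusively on the
anomalies; the climatology and trend are kept so the decomposition can be
inverted (``raw = climatology + trend + anomaly`` wherever raw is defined).

Missing-data rule: any windowed statistic requires at least 80% valid
contributors (the complement of the 20% gap rule used for the 16-day
aggregation windows), otherwise the result is missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from numpy.lib.stride_tricks import sliding_window_view
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .cubes import CELL, TIME, months_of

log = logging.getLogger(__name__)

#: latent heat of vaporization used for the aridity unit conversion [J kg-1]
LAMBDA_VAPORIZATION = 2.5e6
#: W m-2 equivalent of 1 mm day-1 of precipitation
MM_DAY_TO_WM2 = LAMBDA_VAPORIZATION / 86400.0  # ~28.94

#: soil layer weights for the 1-m integral (7, 21 and 72 cm of 100 cm)
SOIL_LAYER_WEIGHTS = (0.07, 0.21, 0.72)

MAX_GAP_FRAC = 0.2


@dataclass
class StaticFields:
    """Per-cell static attributes as a DataFrame wrapper.

    Columns: tree_frac, shrub_frac, grass_frac, soil_frac, irrigation_frac,
    aridity, lat, lon.  Cover fractions must sum to <= 1.
    """

    table: pd.DataFrame

    def __post_init__(self):
        cover = self.table[["tree_frac", "shrub_frac", "grass_frac", "soil_frac"]]
        if (cover.sum(axis=1) > 1 + 1e-6).any():
            raise ValueError("cover fractions sum above 1")

    @property
    def vegetation_cover(self) -> pd.Series:
        t = self.table
        return t["tree_frac"] + t["shrub_frac"] + t["grass_frac"]

    def dominance(self, threshold: float = 0.5) -> pd.Series:
        """Classify tree- vs short-vegetation dominance by tree/(shrub+grass)."""
        t = self.table
        short = t["shrub_frac"] + t["grass_frac"]
        ratio = t["tree_frac"] / short.where(short > 0)
        out = pd.Series("short", index=t.index)
        out[ratio > threshold] = "tree"
        out[short.le(0) & t["tree_frac"].gt(0)] = "tree"
        return out


def aggregate_8daily(
    daily: xr.DataArray,
    step_days: int = 8,
    window_days: int = 16,
    max_gap_frac: float = MAX_GAP_FRAC,
) -> xr.DataArray:
    """Aggregate a daily cube to 8-daily steps with a 16-day moving mean.

    Output step ``k`` averages the 16 consecutive days starting at day
    ``8k`` of the record; successive windows overlap by 8 days.  A window
    with more than ``max_gap_frac`` of its days missing is set to missing.
    The output time stamp is the centre day of each window.
    """
    time = pd.DatetimeIndex(daily[TIME].values)
    dt = np.unique(np.diff(time.values).astype("timedelta64[D]").astype(int))
    if dt.size != 1 or dt[0] != 1:
        raise ValueError("aggregate_8daily requires contiguous daily input")
    vals = daily.values
    n_time = vals.shape[1]
    if n_time < window_days:
        raise ValueError("record shorter than one aggregation window")
    win = sliding_window_view(vals, window_days, axis=1)[:, ::step_days, :]
    valid = np.isfinite(win)
    n_valid = valid.sum(axis=2)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_valid > 0, np.nansum(np.where(valid, win, 0.0), axis=2), np.nan)
        mean = mean / np.where(n_valid > 0, n_valid, 1)
    gap_frac = 1.0 - n_valid / window_days
    mean[gap_frac > max_gap_frac + 1e-12] = np.nan
    centre_idx = np.arange(0, n_time - window_days + 1, step_days) + window_days // 2
    out = xr.DataArray(
        mean,
        dims=(CELL, TIME),
        coords={CELL: daily[CELL].values, TIME: time[centre_idx]},
        name=daily.name,
    )
    for c in ("lat", "lon"):
        if c in daily.coords:
            out = out.assign_coords({c: (CELL, daily[c].values)})
    out.attrs.update(daily.attrs)
    return out


def monthly_climatology(x: xr.DataArray, min_frac: float = 0.8) -> xr.DataArray:
    """Per-cell mean seasonal cycle for each calendar month (1..12).

    The month of a step is taken from its centre date.  A (cell, month)
    entry with fewer than ``min_frac`` of its steps valid is missing.
    """
    months = months_of(x)
    vals = x.values
    out = np.full((vals.shape[0], 12), np.nan)
    for m in range(1, 13):
        sel = months == m
        if not sel.any():
            continue
        sub = vals[:, sel]
        finite = np.isfinite(sub)
        n_valid = finite.sum(axis=1)
        ok = n_valid >= min_frac * sub.shape[1]
        total = np.where(finite, sub, 0.0).sum(axis=1)
        mean = total / np.where(n_valid > 0, n_valid, 1)
        out[ok, m - 1] = mean[ok]
    return xr.DataArray(
        out,
        dims=(CELL, "month"),
        coords={CELL: x[CELL].values, "month": np.arange(1, 13)},
        name=(x.name or "var"),
    )


def _lowess_1d(y: np.ndarray, frac: float, min_points: int) -> np.ndarray:
    x = np.arange(y.size, dtype=float)
    valid = np.isfinite(y)
    if valid.sum() < min_points:
        log.warning("lowess_trend: <%d valid points, falling back to mean", min_points)
        out = np.full(y.size, np.nanmean(y) if valid.any() else np.nan)
        return out
    # it=0: robust re-weighting degenerates on (near-)noise-free series where
    # the residual MAD collapses to zero, so plain local linear fits are used
    sm = _sm_lowess(y[valid], x[valid], frac=frac, it=0, return_sorted=False)
    return np.interp(x, x[valid], sm)


def lowess_trend(x: xr.DataArray, window_frac: float = 0.4, min_points: int = 10) -> xr.DataArray:
    """Locally weighted linear trend with neighbourhood fraction ``window_frac``.

    Applied per cell to a deseasonalized series.  Cells with fewer than
    ``min_points`` valid steps get a constant trend equal to their mean.
    """
    vals = x.values
    trend = np.empty_like(vals)
    for i in range(vals.shape[0]):
        trend[i] = _lowess_1d(vals[i], window_frac, min_points)
    out = x.copy(data=trend)
    out.name = f"{x.name}_trend" if x.name else "trend"
    return out


def compute_anomalies(x: xr.DataArray, window_frac: float = 0.4) -> xr.Dataset:
    """Split an 8-daily cube into climatology + trend + anomaly.

    Order: the monthly climatology is removed first, then the LOWESS trend
    of the deseasonalized residual; the remainder is the anomaly.
    """
    clim = monthly_climatology(x)
    months = months_of(x)
    clim_at_t = clim.values[:, months - 1]
    deseason = x.values - clim_at_t
    trend = lowess_trend(x.copy(data=deseason), window_frac=window_frac)
    anomaly = x.copy(data=deseason - trend.values)
    anomaly.name = "anomaly"
    trend.name = "trend"
    return xr.Dataset({"anomaly": anomaly, "trend": trend, "climatology": clim})


def anomaly_reconstruction(anom: xr.Dataset) -> np.ndarray:
    """climatology(month) + trend + anomaly, the inverse of compute_anomalies."""
    months = months_of(anom["anomaly"])
    clim_at_t = anom["climatology"].values[:, months - 1]
    return clim_at_t + anom["trend"].values + anom["anomaly"].values


def soil_moisture_1m(layer1: xr.DataArray, layer2: xr.DataArray, layer3: xr.DataArray) -> xr.DataArray:
    """Thickness-weighted 1-m soil moisture from the 7/21/72 cm layers."""
    w1, w2, w3 = SOIL_LAYER_WEIGHTS
    out = w1 * layer1 + w2 * layer2 + w3 * layer3
    out.name = "sm_1m"
    out.attrs["units"] = "m3 m-3"
    return out


def build_mask(
    static: StaticFields,
    vod_day: xr.DataArray | None = None,
    vod_night: xr.DataArray | None = None,
    growing_mask: xr.DataArray | None = None,
    min_cover: float = 0.05,
    max_irrigation: float = 0.10,
    apply_vod_criterion: bool = False,
) -> pd.Series:
    """Boolean keep-mask over cells.

    A cell is kept iff vegetation cover >= ``min_cover``, irrigation
    fraction <= ``max_irrigation`` and — for VOD-ratio analyses only —
    its growing-season mean midday VOD does not exceed the midnight mean.
    Cells with missing static attributes are dropped (logged).
    """
    t = static.table
    cover = static.vegetation_cover
    ok = cover.ge(min_cover) & t["irrigation_frac"].le(max_irrigation)
    missing = cover.isna() | t["irrigation_frac"].isna()
    if missing.any():
        log.info("build_mask: dropping %d cells with missing statics", int(missing.sum()))
        ok &= ~missing
    if apply_vod_criterion:
        if vod_day is None or vod_night is None:
            raise ValueError("VOD criterion requested without VOD cubes")
        day = vod_day.values.copy()
        night = vod_night.values.copy()
        if growing_mask is not None:
            season = growing_mask.values.astype(bool)
            day = np.where(season, day, np.nan)
            night = np.where(season, night, np.nan)
        with np.errstate(invalid="ignore"):
            day_mean = np.nanmean(day, axis=1)
            night_mean = np.nanmean(night, axis=1)
        ok &= pd.Series(day_mean <= night_mean, index=t.index)
    return ok


def aridity_index(
    net_radiation_mean,
    precip_mean_mm_day,
    lam: float = LAMBDA_VAPORIZATION,
) -> np.ndarray:
    """Aridity index: mean net radiation over energy-converted precipitation.

    AI = Rn / (lam/86400 * P[mm day-1]); AI > 1 dry, <= 1 wet.  Cells with
    zero precipitation map to +inf.
    """
    rn = np.asarray(net_radiation_mean, dtype=float)
    p = np.asarray(precip_mean_mm_day, dtype=float)
    conv = lam / 86400.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where(p > 0, rn / (conv * p), np.inf)
    if np.any(p <= 0):
        log.warning("aridity_index: %d cells with non-positive precipitation", int((p <= 0).sum()))
    return ai
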