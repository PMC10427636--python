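"""Composite trajectories, aridity/phase bins and bootstrap significance.

Reproduces the statistics behind the trajectory and bin summaries: plain
(unweighted) means across grid cells with a spatial standard error from an
every-third-cell subsample, quantile aridity classes with near-equal cell
counts, the physio/total median ratio over the drought window, and a
seasonal-null bootstrap significance flag per cell with a >60% bin dot.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

from .cubes import CELL, TIME

log = logging.getLogger(__name__)


def _subsample_cells(lat: np.ndarray, lon: np.ndarray, stride: int = 3,
                     offset=(0, 0)) -> np.ndarray:
    """Boolean mask of cells at every `stride`-th latitude and longitude."""
    lat_idx = np.searchsorted(np.unique(lat), lat)
    lon_idx = np.searchsorted(np.unique(lon), lon)
    return ((lat_idx - offset[0]) % stride == 0) & ((lon_idx - offset[1]) % stride == 0)


def composite_trajectory(
    traj: xr.Dataset,
    lat: pd.Series,
    lon: pd.Series,
    min_valid: int = 20,
    stride: int = 3,
    offset=(0, 0),
) -> pd.DataFrame:
    """Mean trajectory across cells with a spatial standard error.

    Cells need >= ``min_valid`` of the 24 window steps.  The SE per step is
    the standard deviation over the every-third-cell subsample divided by
    the square root of the subsample size (reducing the influence of
    spatial autocorrelation); the mean itself uses all cells, unweighted.
    """
    ok = traj["valid_count"].values >= min_valid
    cells = traj[CELL].values[ok]
    if cells.size == 0:
        return pd.DataFrame(columns=["mean", "se", "n", "n_subsample"])
    vals = traj["trajectory"].values[ok]
    la = lat.loc[cells].values
    lo = lon.loc[cells].values
    sub = _subsample_cells(la, lo, stride, offset)
    with np.errstate(all="ignore"):
        mean = np.nanmean(vals, axis=0)
        sub_vals = vals[sub]
        n_sub = np.isfinite(sub_vals).sum(axis=0)
        sd = np.nanstd(sub_vals, axis=0, ddof=1)
    se = np.where(n_sub > 1, sd / np.sqrt(np.maximum(n_sub, 1)), np.nan)
    return pd.DataFrame(
        {
            "mean": mean,
            "se": se,
            "n": np.isfinite(vals).sum(axis=0),
            "n_subsample": n_sub,
        },
        index=pd.Index(traj["rel_step"].values, name="rel_step"),
    )


def assign_aridity_classes(aridity: pd.Series, n_classes: int = 6):
    """Quantile classes of the aridity index with near-equal cell counts."""
    labels, edges = pd.qcut(aridity, n_classes, labels=False, retbins=True,
                            duplicates="drop")
    return labels.astype(int), edges


def bin_medians(
    values: pd.DataFrame, aridity_class: pd.Series
) -> pd.DataFrame:
    """Median of per-cell values within each (aridity class x phase) bin.

    ``values``: one row per cell, one column per drought phase.  Empty bins
    are missing."""
    df = values.join(aridity_class.rename("aridity_class"), how="inner")
    return df.groupby("aridity_class").median()


def physio_total_ratio(
    physio_median: pd.Series,
    total_median: pd.Series,
    aridity_class: pd.Series,
    eps: float = 1e-12,
) -> pd.Series:
    """Per-class median of the per-cell ratio between drought-window median
    physiological and total anomalies; cells with |total| < eps skipped."""
    df = pd.DataFrame(
        {"physio": physio_median, "total": total_median, "cls": aridity_class}
    ).dropna()
    small = df["total"].abs() < eps
    if small.any():
        log.info("physio_total_ratio: skipping %d cells with ~zero total", int(small.sum()))
    df = df[~small]
    ratio = df["physio"] / df["total"]
    return ratio.groupby(df["cls"]).median()


def seasonal_null_pool(
    anom: xr.DataArray,
    peak_step: int,
    drought_year: int,
    window_steps: int = 2,
) -> dict[int, np.ndarray]:
    """Same-season null values per cell: anomalies within +-``window_steps``
    of the peak's calendar position in every non-drought year."""
    time = pd.DatetimeIndex(anom[TIME].values)
    peak_doy = time[peak_step].dayofyear
    doy = time.dayofyear.values.astype(float)
    ddoy = np.minimum(np.abs(doy - peak_doy), 365.25 - np.abs(doy - peak_doy))
    near = ddoy <= window_steps * 8 + 4
    pool_steps = near & (time.year.values != drought_year)
    vals = anom.values[:, pool_steps]
    return {int(c): vals[i][np.isfinite(vals[i])]
            for i, c in enumerate(anom[CELL].values)}


def bootstrap_significance(
    observed: pd.Series,
    pools: dict[int, np.ndarray],
    n_samples: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    min_pool: int = 10,
) -> pd.Series:
    """Flag cells whose observed anomaly falls outside the 2.5-97.5
    percentile range of ``n_samples`` draws (with replacement) from the
    cell's seasonal null pool.  Pools smaller than ``min_pool`` leave the
    cell unflagged (logged).  Reproducible bit-exactly from the seed."""
    rng = np.random.default_rng(seed)
    out = {}
    for c, obs in observed.items():
        pool = pools.get(int(c), np.empty(0))
        if pool.size < min_pool or not np.isfinite(obs):
            if pool.size < min_pool:
                log.info("bootstrap_significance: cell %s pool too small", c)
            out[c] = False
            continue
        draws = rng.choice(pool, size=n_samples, replace=True)
        lo, hi = np.percentile(draws, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        out[c] = bool(obs < lo or obs > hi)
    return pd.Series(out, name="significant")


def bin_dot(flags: pd.Series, aridity_class: pd.Series, threshold: float = 0.6) -> pd.Series:
    """Bin marker: set iff more than ``threshold`` of the bin's cells are
    individually significant (strict inequality)."""
    df = pd.DataFrame({"flag": flags, "cls": aridity_class}).dropna()
    frac = df.groupby("cls")["flag"].mean()
    return frac > threshold
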