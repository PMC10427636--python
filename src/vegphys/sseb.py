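"""Simplified surface energy balance (SSEB): midday LST -> daily ET.

The model reads the midday surface-air temperature gradient as the sensible
heat fraction of available energy and assigns the remainder to latent heat:

    ET = (1 - Cp * rho * (LSTmax - Tamax) * (A * ga) / (A * Rsmax)) * Rnmean

with ET the daily latent heat flux [W m-2], LSTmax the midday land-surface
temperature [K], Tamax the maximum hourly air temperature [K], Rsmax the
maximum hourly net shortwave radiation [W m-2], Rnmean the daily mean net
radiation [W m-2], Cp = 1005 J kg-1 K-1, rho = 1.23 kg m-3, and ga the
cover-weighted aerodynamic conductance [m s-1].  A is the diurnal-amplitude
multiplier (1.4) applied to both ga and Rsmax; it is kept explicit for
sensitivity checks even though it cancels algebraically.  Daily minimum
surface and air temperatures are assumed equal, so only the maxima enter.

ET == Rnmean exactly when LSTmax == Tamax, and ET decreases linearly in the
surface-air gradient; the closed-form inverse below is used by the synthetic
generator to manufacture LST from a prescribed ET.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

from .cubes import CELL, TIME

log = logging.getLogger(__name__)

CP = 1005.0  # specific heat capacity of air [J kg-1 K-1]
RHO = 1.23  # simplified air density [kg m-3]
AMP_FACTOR = 1.4  # diurnal-amplitude multiplier on ga and Rsmax

#: aerodynamic conductance by surface type [m s-1]
GA_TREE = 0.06
GA_SHORT = 0.0345  # shrub + grass
GA_SOIL = 0.002


def mix_ga(tree_frac, short_frac, soil_frac) -> np.ndarray:
    """Cover-weighted aerodynamic conductance.

    Residual cover (1 - sum of fractions) is treated as soil by the caller;
    fractions summing above 1 are rejected.
    """
    tree = np.asarray(tree_frac, dtype=float)
    short = np.asarray(short_frac, dtype=float)
    soil = np.asarray(soil_frac, dtype=float)
    total = tree + short + soil
    if np.any(total > 1 + 1e-6):
        raise ValueError("cover fractions sum above 1")
    return GA_TREE * tree + GA_SHORT * short + GA_SOIL * soil


def mix_ga_static(static) -> pd.Series:
    """ga per cell from a StaticFields table; residual cover counts as soil."""
    t = static.table
    short = t["shrub_frac"] + t["grass_frac"]
    soil = (1.0 - t["tree_frac"] - short).clip(lower=0.0)
    ga = mix_ga(t["tree_frac"].values, short.values, soil.values)
    return pd.Series(ga, index=t.index, name="ga")


def daily_met_summaries(
    ta_hourly: xr.DataArray,
    rs_hourly: xr.DataArray,
    rn_hourly: xr.DataArray,
    min_valid_frac: float = 0.8,
) -> xr.Dataset:
    """Reduce hourly met cubes to the per-day inputs of the SSEB model.

    Returns ``tamax`` (max hourly air temperature), ``rsmax`` (max hourly
    net shortwave) and ``rnmean`` (daily mean net radiation).  Days with
    fewer than ``min_valid_frac`` of their 24 hours valid are missing.
    """
    time = pd.DatetimeIndex(ta_hourly[TIME].values)
    if len(time) % 24 != 0:
        raise ValueError("hourly record length is not a whole number of days")
    n_days = len(time) // 24

    def _daily(cube, reducer):
        v = cube.values.reshape(cube.shape[0], n_days, 24)
        n_valid = np.isfinite(v).sum(axis=2)
        with np.errstate(invalid="ignore", all="ignore"):
            out = reducer(v)
        out[n_valid < min_valid_frac * 24] = np.nan
        return out

    tamax = _daily(ta_hourly, lambda v: np.nanmax(v, axis=2))
    rsmax = _daily(rs_hourly, lambda v: np.nanmax(v, axis=2))
    rnmean = _daily(rn_hourly, lambda v: np.nanmean(v, axis=2))
    days = time[::24].normalize()
    coords = {CELL: ta_hourly[CELL].values, TIME: days}
    return xr.Dataset(
        {
            "tamax": ((CELL, TIME), tamax),
            "rsmax": ((CELL, TIME), rsmax),
            "rnmean": ((CELL, TIME), rnmean),
        },
        coords=coords,
    )


def estimate_et(
    lst_max,
    ta_max,
    rs_max,
    rn_mean,
    ga,
    amp_factor: float = AMP_FACTOR,
    clip: bool = True,
):
    """Daily latent heat flux [W m-2] from the SSEB bracket formula.

    ``rs_max <= 0`` yields missing (division guard).  When ``clip`` is on,
    results are limited to [0, rn_mean] for rn_mean > 0 and clipping events
    are logged.
    """
    lst_max = np.asarray(lst_max, dtype=float)
    ta_max = np.asarray(ta_max, dtype=float)
    rs_max = np.asarray(rs_max, dtype=float)
    rn_mean = np.asarray(rn_mean, dtype=float)
    ga = np.asarray(ga, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        bracket = 1.0 - CP * RHO * (lst_max - ta_max) * (amp_factor * ga) / (amp_factor * rs_max)
    et = bracket * rn_mean
    et = np.where(rs_max > 0, et, np.nan)
    if clip:
        pos = rn_mean > 0
        lo = np.where(pos & (et < 0), 0.0, et)
        hi = np.where(pos & (lo > rn_mean), rn_mean, lo)
        n_clip = int(np.sum(pos & np.isfinite(et) & ((et < 0) | (et > rn_mean))))
        if n_clip:
            log.info("estimate_et: clipped %d values into [0, Rnmean]", n_clip)
        et = hi
    return et if et.shape else float(et)


def invert_lst(et_true, ta_max, rs_max, rn_mean, ga, amp_factor: float = AMP_FACTOR):
    """Exact algebraic inverse of :func:`estimate_et`.

    Returns the LSTmax for which the forward model reproduces ``et_true``.
    Valid for 0 <= et_true <= rn_mean with rn_mean > 0 and rs_max > 0;
    values outside the domain raise.
    """
    et_true = np.asarray(et_true, dtype=float)
    ta_max = np.asarray(ta_max, dtype=float)
    rs_max = np.asarray(rs_max, dtype=float)
    rn_mean = np.asarray(rn_mean, dtype=float)
    ga = np.asarray(ga, dtype=float)
    finite = np.isfinite(et_true) & np.isfinite(rn_mean)
    if np.any(finite & (et_true > rn_mean * (1 + 1e-12))):
        raise ValueError("et_true exceeds rn_mean: outside the invertible domain")
    if np.any(finite & (rn_mean <= 0)):
        raise ValueError("rn_mean must be positive on the invertible domain")
    grad = (1.0 - et_true / rn_mean) * (amp_factor * rs_max) / (CP * RHO * amp_factor * ga)
    out = ta_max + grad
    return out if out.shape else float(out)
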