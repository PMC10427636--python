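"""Synthetic gridded ecohydrology with a known physiological drought signal.

The generator emulates the data situation of the observational analysis:
multi-year gridded hydro-meteorology (temperature, shortwave radiation,
VPD, precipitation, bucket-model soil moisture), vegetation structure
(LAI, NIRv) and observation streams (SIF and NIR radiance, midday LST,
midday/midnight VOD) on exchangeable 0.25-degree-style cells, with

* a 40-year daily soil-moisture record whose monthly means feed the
  drought-ranking rule,
* a prescribed drought: precipitation suppressed for a fixed window of the
  designated drought year in the configured drought cells, deep enough to
  produce the 40-year soil-moisture minimum there,
* a lagged structural response: LAI follows (smoothed, lagged) soil
  moisture, and
* a faster physiological downregulation factor phi(t) in (0, 1] imprinted
  multiplicatively on SIF and ET and through a day/night asymmetry on VOD:

      phi = min(1, (SM / SM_crit)^a) * exp(-b * max(0, VPD - VPD_clim))

  raised to a per-cell severity exponent that increases with aridity and
  decreases with tree cover (the planted spatial drivers for the
  attribution stage).  SM_crit is tied to each cell's own non-drought
  5th-percentile soil moisture, so phi == 1 under climatological moisture
  and VPD.

Everything is reproducible bit-for-bit from the master seed; each variable
draws from its own RNG stream so adding a stream never perturbs others.
All latent components (phi, noise-free structural parts, the per-stream
physiological imprints, true ET) are returned in a truth dataset for
recovery tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy.signal import lfilter

from . import sseb
from .cubes import CELL, TIME, make_cube
from .preprocess import StaticFields

__all__ = [
    "SimConfig",
    "SimBundle",
    "generate_static",
    "generate_met",
    "generate_observations",
    "generate_ensemble",
]

_DEFAULT_NOISE = {
    "lai": 0.1,
    "nirv": 0.1,
    "sif": 0.1,
    "nir": 0.05,
    "lst": 0.1,
    "vod": 0.1,
}


@dataclass
class SimConfig:
    """Study conditions of the synthetic ensemble.

    Noise levels are fractions of each stream's signal standard deviation;
    ``met_anomaly_sd`` scales the AR(1) weather anomalies relative to the
    seasonal amplitude (0 gives purely periodic forcing).
    """

    n_cells: int = 200
    n_years: int = 5
    record_years: int = 40
    time_step_days: int = 8
    seed: int = 0
    drought_cells: tuple | None = None  # default: first half of the cells
    drought_year_offset: int = -2  # drought year relative to the last study year
    drought_start_doy: int = 121  # suppression ends as climatological rains return
    drought_length_steps: int = 15  # 8-day steps of precipitation suppression
    drought_precip_factor: float = 0.05
    met_anomaly_sd: float = 0.1
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE))
    aridity_range: tuple = (0.5, 2.0)
    phys_sensitivity: tuple = (1.0, 0.4)  # (a on SM/SM_crit, b per kPa VPD excess)
    structural_lag_steps: int = 2
    lai_memory_days: int = 64  # soil-moisture integration window behind LAI
    lai_moisture_coupling: float = 0.3  # fractional LAI loss at wsat = 0
    sm_crit_frac: float = 0.85  # of the non-drought 5th-percentile soil moisture
    vod_delta: float = 0.3  # day/night asymmetry at phi = 0
    vod_scale: float = 0.25  # VOD per unit biomass proxy
    sif_scale: float = 1.5  # mW m-2 sr-1 nm-1 at full cover, phi = 1
    nir_base: float = 40.0
    nirv_scale: float = 0.4
    porosity: float = 0.45
    field_capacity: float = 0.35
    residual_sm: float = 0.02
    demand_fraction: float = 0.5  # ET demand as a fraction of daily net radiation
    end_year: int = 2021

    def __post_init__(self):
        if self.n_cells <= 0 or self.n_years <= 0:
            raise ValueError("n_cells and n_years must be positive")
        if self.n_years < 5:
            raise ValueError("at least 5 study years are required")
        if self.record_years < self.n_years:
            raise ValueError("record must contain the study period")
        if self.drought_cells is None:
            self.drought_cells = tuple(range(self.n_cells // 2))
        if any(c < 0 or c >= self.n_cells for c in self.drought_cells):
            raise ValueError("drought_cells outside the cell range")
        if any(v < 0 for v in self.noise_sd.values()) or self.met_anomaly_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.drought_length_steps <= 0:
            raise ValueError("drought_length_steps must be positive")

    # -- derived calendar quantities -------------------------------------
    @property
    def study_years(self) -> range:
        return range(self.end_year - self.n_years + 1, self.end_year + 1)

    @property
    def record_start_year(self) -> int:
        return self.end_year - self.record_years + 1

    @property
    def drought_year(self) -> int:
        return self.end_year + self.drought_year_offset + 1

    def rng(self, stream: str) -> np.random.Generator:
        """Independent RNG per named variable, split from the master seed."""
        tag = zlib.crc32(stream.encode())
        return np.random.default_rng(np.random.SeedSequence((self.seed, tag)))


@dataclass
class SimBundle:
    static: StaticFields
    met_record: xr.Dataset  # daily, full 40-year record
    sm_monthly: xr.DataArray  # monthly means of 1-m soil moisture, 40 years
    met_daily: xr.Dataset  # daily, study window (incl. soil layers, VPD)
    met_hourly: xr.Dataset  # hourly ta/swnet/rn, study window
    met_8daily: xr.Dataset  # wind and pressure, directly 8-daily
    summaries: xr.Dataset  # daily tamax/rsmax/rnmean from the hourly cubes
    obs: xr.Dataset | None = None
    truth: xr.Dataset | None = None


# ---------------------------------------------------------------------------
# static fields
# ---------------------------------------------------------------------------

def generate_static(config: SimConfig) -> StaticFields:
    n = config.n_cells
    rng = config.rng("static")
    ncols = int(np.ceil(np.sqrt(n)))
    idx = np.arange(n)
    lat = 40.0 + 0.25 * (idx // ncols)
    lon = 10.0 + 0.25 * (idx % ncols)

    aridity = np.linspace(*config.aridity_range, n)
    rng.shuffle(aridity)

    tree = rng.uniform(0.0, 0.85, n)
    cover_total = rng.uniform(0.55, 0.95, n)
    tree = np.minimum(tree, cover_total)
    short = cover_total - tree
    grass_share = rng.uniform(0.3, 0.7, n)
    grass = short * grass_share
    shrub = short - grass
    irrigation = rng.uniform(0.0, 0.05, n)

    # a few cells violating the analysis masks, outside the drought set
    sparse = [n - 1, n - 2]
    irrigated = [n - 3, n - 4, n - 5]
    for c in sparse:
        scale = 0.03 / max(cover_total[c], 1e-9)
        tree[c] *= scale
        shrub[c] *= scale
        grass[c] *= scale
    for c in irrigated:
        irrigation[c] = 0.2

    soil = 1.0 - tree - shrub - grass
    table = pd.DataFrame(
        {
            "tree_frac": tree,
            "shrub_frac": shrub,
            "grass_frac": grass,
            "soil_frac": soil,
            "irrigation_frac": irrigation,
            "aridity": aridity,
            "lat": lat,
            "lon": lon,
        },
        index=pd.Index(idx, name="cell"),
    )
    return StaticFields(table)


# ---------------------------------------------------------------------------
# meteorology
# ---------------------------------------------------------------------------

def _ar1(rng, shape, rho=0.9, sd=1.0):
    if sd == 0:
        return np.zeros(shape)
    eps = rng.standard_normal(shape)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    return lfilter([innov_sd], [1.0, -rho], eps, axis=-1)


def _seasonal(doy, mean, amp, phase_doy=110.0):
    return mean + amp * np.sin(2 * np.pi * (doy - phase_doy) / 365.25)


def _es_kpa(t_celsius):
    return 0.6108 * np.exp(17.27 * t_celsius / (t_celsius + 237.3))


def _eight_daily_centres(time_daily: pd.DatetimeIndex) -> pd.DatetimeIndex:
    n = len(time_daily)
    centre_idx = np.arange(0, n - 16 + 1, 8) + 8
    return time_daily[centre_idx]


def generate_met(config: SimConfig, static: StaticFields | None = None) -> SimBundle:
    """Generate the full meteorological forcing and soil-moisture record."""
    if static is None:
        static = generate_static(config)
    n = config.n_cells
    aridity = static.table["aridity"].values[:, None]

    spinup = pd.date_range(f"{config.record_start_year - 1}-01-01",
                           f"{config.record_start_year - 1}-12-31", freq="D")
    record = pd.date_range(f"{config.record_start_year}-01-01",
                           f"{config.end_year}-12-31", freq="D")
    time = spinup.append(record)
    doy = time.dayofyear.values[None, :]
    n_t = len(time)

    cell_offset = config.rng("ta_offset").uniform(-1.5, 1.5, (n, 1))
    ta_clim = _seasonal(doy, 283.15, 12.0) + cell_offset  # K
    ta = ta_clim + _ar1(config.rng("ta"), (n, n_t), rho=0.9,
                        sd=12.0 * config.met_anomaly_sd)

    sw_clim = _seasonal(doy, 170.0, 130.0)
    sw = np.maximum(
        20.0, sw_clim + _ar1(config.rng("swnet"), (n, n_t), rho=0.8,
                             sd=130.0 * config.met_anomaly_sd)
    )
    rn = 0.75 * sw - 40.0  # daily mean net radiation [W m-2]

    # precipitation: mean set by the target aridity, mild winter-wet cycle
    rn_pos_mean = np.maximum(rn, 0.0).mean(axis=1, keepdims=True)
    from .preprocess import MM_DAY_TO_WM2

    p_mean = rn_pos_mean / (MM_DAY_TO_WM2 * aridity)  # mm day-1
    # summer-dry seasonality (minimum ~early June): climatological rains are
    # already recovering when the imposed suppression window ends, so the
    # suppression window itself controls the timing of the soil-moisture
    # minimum rather than the seasonal cycle
    p_season = 1.0 + 0.35 * np.sin(2 * np.pi * (doy - 251) / 365.25)
    p_mult = np.maximum(0.0, 1.0 + _ar1(config.rng("precip"), (n, n_t), rho=0.7,
                                        sd=3.0 * config.met_anomaly_sd))
    precip = p_mean * p_season * p_mult

    # drought: suppress precipitation in the drought cells
    dlen_days = config.drought_length_steps * config.time_step_days
    in_window = (
        (time.year.values == config.drought_year)
        & (time.dayofyear.values >= config.drought_start_doy)
        & (time.dayofyear.values < config.drought_start_doy + dlen_days)
    )
    dcells = np.asarray(config.drought_cells, dtype=int)
    suppress = np.ones((n, n_t))
    suppress[np.ix_(dcells, np.where(in_window)[0])] = config.drought_precip_factor
    precip = precip * suppress

    # bucket soil moisture: inflow precipitation, outflow demand-proportional,
    # fast drainage above field capacity; 1-m column (1000 mm)
    pet = 0.0346 * np.maximum(rn, 0.0)  # mm day-1, latent-heat equivalent of Rn
    sm = np.empty((n, n_t))
    s = np.full(n, config.field_capacity)
    por = config.porosity
    fc = config.field_capacity
    for t in range(n_t):
        e = pet[:, t] * s / por
        s = s + (precip[:, t] - e) / 1000.0 - 0.25 * np.maximum(0.0, s - fc)
        s = np.clip(s, config.residual_sm, por)
        sm[:, t] = s

    # drop the spin-up year
    keep = slice(len(spinup), None)
    time = record
    doy = doy[:, keep]
    ta, sw, rn, precip, sm = (a[:, keep] for a in (ta, sw, rn, precip, sm))
    ta_clim = ta_clim[:, keep]

    # VPD: seasonal baseline from temperature plus a soil-dryness coupling
    vpd_clim = 0.4 * _es_kpa(ta_clim - 273.15)
    s_ref = np.minimum(por / np.maximum(aridity, 1.0), fc)
    deficit = np.maximum(0.0, s_ref - sm) / por
    vpd = np.maximum(
        0.01,
        vpd_clim * (1.0 + _ar1(config.rng("vpd"), (n, len(time)), rho=0.85,
                               sd=2.5 * config.met_anomaly_sd))
        + 1.2 * vpd_clim * deficit,
    )

    lat = static.table["lat"].values
    lon = static.table["lon"].values

    def cube(vals, units, name, tindex=time):
        return make_cube(vals, tindex, lat=lat, lon=lon, units=units, name=name)

    met_record = xr.Dataset(
        {
            "ta": cube(ta, "K", "ta"),
            "swnet": cube(sw, "W m-2", "swnet"),
            "rn": cube(rn, "W m-2", "rn"),
            "precip": cube(precip, "mm day-1", "precip"),
            "sm": cube(sm, "m3 m-3", "sm"),
        }
    )
    met_record.attrs["vpd_note"] = "vpd only provided for the study window"

    sm_monthly = (
        met_record["sm"].resample({TIME: "MS"}).mean()
    )
    sm_monthly.name = "sm_monthly"

    # study-window slices
    study = time.year >= config.study_years.start
    t_study = time[study]
    ta_s, sw_s, rn_s, precip_s, sm_s, vpd_s = (
        a[:, study] for a in (ta, sw, rn, precip, sm, vpd)
    )
    # soil layers engineered so the 7/21/72 cm weighting returns sm exactly
    c3 = (1.0 - 0.07 * 0.8 - 0.21 * 0.9) / 0.72
    met_daily = xr.Dataset(
        {
            "ta": cube(ta_s, "K", "ta", t_study),
            "swnet": cube(sw_s, "W m-2", "swnet", t_study),
            "rn": cube(rn_s, "W m-2", "rn", t_study),
            "precip": cube(precip_s, "mm day-1", "precip", t_study),
            "vpd": cube(vpd_s, "kPa", "vpd", t_study),
            "vpd_clim": cube(np.broadcast_to(vpd_clim[:, study], vpd_s.shape).copy(),
                             "kPa", "vpd_clim", t_study),
            "sm": cube(sm_s, "m3 m-3", "sm", t_study),
            "sm_layer1": cube(0.8 * sm_s, "m3 m-3", "sm_layer1", t_study),
            "sm_layer2": cube(0.9 * sm_s, "m3 m-3", "sm_layer2", t_study),
            "sm_layer3": cube(c3 * sm_s, "m3 m-3", "sm_layer3", t_study),
        }
    )

    # hourly sub-grid for the SSEB inputs only (ta, swnet, rn)
    hours = np.arange(24)
    diurnal_ta = -np.cos(2 * np.pi * (hours - 14) / 24.0)  # peak at 14 h
    half_sine = np.where(
        (hours >= 6) & (hours < 18), np.sin(np.pi * (hours - 6) / 12.0), 0.0
    )
    sw_shape = half_sine / half_sine.mean()  # unit mean, peak ~ pi
    n_days = len(t_study)
    ta_h = (ta_s[:, :, None] + 3.0 * diurnal_ta[None, None, :]).reshape(n, n_days * 24)
    sw_h = (sw_s[:, :, None] * sw_shape[None, None, :]).reshape(n, n_days * 24)
    rn_h = 0.75 * sw_h - 40.0
    t_hourly = pd.date_range(t_study[0], periods=n_days * 24, freq="h")
    met_hourly = xr.Dataset(
        {
            "ta": cube(ta_h, "K", "ta", t_hourly),
            "swnet": cube(sw_h, "W m-2", "swnet", t_hourly),
            "rn": cube(rn_h, "W m-2", "rn", t_hourly),
        }
    )

    t8 = _eight_daily_centres(t_study)
    wind = 3.0 + _ar1(config.rng("wind"), (n, len(t8)), rho=0.6,
                      sd=5.0 * config.met_anomaly_sd)
    pressure = 101325.0 + _ar1(config.rng("pressure"), (n, len(t8)), rho=0.6,
                               sd=3000.0 * config.met_anomaly_sd)
    met_8daily = xr.Dataset(
        {
            "wind": cube(wind, "m s-1", "wind", t8),
            "pressure": cube(pressure, "Pa", "pressure", t8),
        }
    )

    summaries = sseb.daily_met_summaries(
        met_hourly["ta"], met_hourly["swnet"], met_hourly["rn"]
    )

    return SimBundle(
        static=static,
        met_record=met_record,
        sm_monthly=sm_monthly,
        met_daily=met_daily,
        met_hourly=met_hourly,
        met_8daily=met_8daily,
        summaries=summaries,
    )


# ---------------------------------------------------------------------------
# observation streams
# ---------------------------------------------------------------------------

def _trailing_mean(x: np.ndarray, window: int, lag: int) -> np.ndarray:
    """Mean of x over the `window` days ending `lag` days before each day."""
    n, t = x.shape
    csum = np.cumsum(np.concatenate([np.zeros((n, 1)), x], axis=1), axis=1)
    out = np.empty_like(x)
    for j in range(t):
        hi = max(j - lag + 1, 1)
        lo = max(hi - window, 0)
        out[:, j] = (csum[:, hi] - csum[:, lo]) / max(hi - lo, 1)
    return out


def _phi(config: SimConfig, sm, vpd, vpd_clim, sm_crit, severity):
    a, b = config.phys_sensitivity
    base = np.ones_like(sm)
    if a > 0:
        base = np.minimum(1.0, (sm / sm_crit) ** a)
    vpd_excess = np.maximum(0.0, vpd - vpd_clim)
    phi = base * np.exp(-b * vpd_excess)
    return np.clip(phi, 1e-6, 1.0) ** severity


def generate_observations(
    met: SimBundle, config: SimConfig
) -> tuple[xr.Dataset, xr.Dataset]:
    """Build the observation streams and the latent truth from the forcing."""
    for v in ("ta", "swnet", "rn", "precip", "vpd", "sm"):
        if v not in met.met_daily:
            raise ValueError(f"missing met variable: {v}")
    static = met.static
    n = config.n_cells
    t_study = pd.DatetimeIndex(met.met_daily[TIME].values)
    n_days = len(t_study)
    sm = met.met_daily["sm"].values
    vpd = met.met_daily["vpd"].values
    vpd_clim = met.met_daily["vpd_clim"].values
    ta_clim_proxy = met.met_daily["ta"].values

    # physiological downregulation ---------------------------------------
    drought_mask = np.zeros(n_days, dtype=bool)
    dlen_days = config.drought_length_steps * config.time_step_days
    in_window = (
        (t_study.year == config.drought_year)
        & (t_study.dayofyear >= config.drought_start_doy)
        & (t_study.dayofyear < config.drought_start_doy + dlen_days + 90)
    )
    drought_mask[in_window] = True
    non_drought_sm = np.where(drought_mask[None, :], np.nan, sm)
    p5 = np.nanpercentile(non_drought_sm, 5, axis=1)[:, None]
    sm_crit = config.sm_crit_frac * p5

    ai = static.table["aridity"].values[:, None]
    ai_lo, ai_hi = config.aridity_range
    ai_norm = np.clip((ai - ai_lo) / max(ai_hi - ai_lo, 1e-9), 0, 1)
    tree = static.table["tree_frac"].values[:, None]
    severity = (0.45 + 0.7 * ai_norm) * (1.4 - 0.7 * tree)
    phi = _phi(config, sm, vpd, vpd_clim, sm_crit, severity)

    # vegetation structure -----------------------------------------------
    ta_c = ta_clim_proxy - 273.15
    doy = t_study.dayofyear.values[None, :]
    shape = 0.15 + 0.85 * np.clip(
        (_seasonal(doy, 10.0, 12.0) - (-2.0)) / 24.0, 0.0, 1.0
    )
    # structure responds with a lag and considerable inertia, and much more
    # weakly than physiology: a few months of drought dent LAI by ~10%, they
    # do not halve it (leaf area integrates moisture over months)
    lag_days = config.structural_lag_steps * config.time_step_days
    sm_lag = _trailing_mean(sm, config.lai_memory_days, lag_days)
    wsat = np.clip(sm_lag / config.field_capacity, 0.0, 1.0)
    lai_max = 1.5 + 3.0 * static.table["tree_frac"].values[:, None]
    lai_true = lai_max * shape * (
        1.0 - config.lai_moisture_coupling * (1.0 - wsat)
    )
    f_struct = 1.0 - np.exp(-0.5 * lai_true)  # light interception

    # observation streams -------------------------------------------------
    def noise(stream, signal):
        # noise at `sd` times each cell's own temporal signal SD, so cells
        # with large structural offsets do not inflate other cells' noise
        sd = config.noise_sd.get(stream, 0.0)
        if sd == 0:
            return np.zeros_like(signal)
        scale = np.nanstd(signal, axis=1, keepdims=True)
        scale = np.where(np.isfinite(scale), scale, 0.0)
        return config.rng("noise_" + stream).standard_normal(signal.shape) * sd * scale

    lai_obs = np.maximum(0.0, lai_true + noise("lai", lai_true))
    nirv = np.maximum(0.0, config.nirv_scale * f_struct + noise("nirv", f_struct))
    sif_core = config.sif_scale * f_struct * phi
    sif = sif_core + noise("sif", sif_core)
    nir_core = config.nir_base * (0.6 + 0.4 * f_struct)
    nir = np.maximum(1e-6, nir_core + noise("nir", nir_core))

    biomass = 0.5 + 0.5 * _trailing_mean(lai_true, 24, 0) + 2.2 * tree
    vod_night_core = config.vod_scale * biomass
    vod_day_core = vod_night_core * (1.0 - config.vod_delta * (1.0 - phi))
    vod_sd = config.noise_sd.get("vod", 0.0) * np.nanstd(
        vod_night_core, axis=1, keepdims=True
    )
    vod_night = vod_night_core + config.rng("noise_vod_night").standard_normal(
        vod_night_core.shape
    ) * vod_sd
    vod_day = vod_day_core + config.rng("noise_vod_day").standard_normal(
        vod_day_core.shape
    ) * vod_sd

    # ET and midday LST ----------------------------------------------------
    summ = met.summaries
    tamax = summ["tamax"].values
    rsmax = summ["rsmax"].values
    rnmean = summ["rnmean"].values
    ga = sseb.mix_ga_static(static).values[:, None]
    valid = (rnmean > 20.0) & (rsmax > 0)
    et_true = np.where(
        valid, config.demand_fraction * np.maximum(rnmean, 0.0) * f_struct * phi, np.nan
    )
    lst_core = np.full_like(et_true, np.nan)
    lst_core[valid] = sseb.invert_lst(
        et_true[valid],
        np.broadcast_to(tamax, et_true.shape)[valid],
        np.broadcast_to(rsmax, et_true.shape)[valid],
        np.broadcast_to(rnmean, et_true.shape)[valid],
        np.broadcast_to(ga, et_true.shape)[valid],
    )
    grad_sd = np.nanstd(lst_core - tamax, axis=1, keepdims=True)
    grad_sd = np.where(np.isfinite(grad_sd), grad_sd, 0.0)
    lst = lst_core + config.rng("noise_lst").standard_normal(lst_core.shape) * (
        config.noise_sd.get("lst", 0.0) * grad_sd
    )

    lat = static.table["lat"].values
    lon = static.table["lon"].values

    def cube(vals, units, name):
        return make_cube(vals, t_study, lat=lat, lon=lon, units=units, name=name)

    obs = xr.Dataset(
        {
            "lai": cube(lai_obs, "m2 m-2", "lai"),
            "nirv": cube(nirv, "-", "nirv"),
            "sif": cube(sif, "mW m-2 sr-1 nm-1", "sif"),
            "nir_radiance": cube(nir, "mW m-2 sr-1 nm-1", "nir_radiance"),
            "lst_midday": cube(lst, "K", "lst_midday"),
            "vod_day": cube(vod_day, "-", "vod_day"),
            "vod_night": cube(vod_night, "-", "vod_night"),
        }
    )

    sifrel_struct = config.sif_scale * f_struct / nir_core
    et_struct = np.where(
        valid, config.demand_fraction * np.maximum(rnmean, 0.0) * f_struct, np.nan
    )
    truth = xr.Dataset(
        {
            "phi": cube(phi, "-", "phi"),
            "soil_moisture_truth": cube(sm, "m3 m-3", "soil_moisture_truth"),
            "lai_true": cube(lai_true, "m2 m-2", "lai_true"),
            "sifrel_struct": cube(sifrel_struct, "-", "sifrel_struct"),
            "sifrel_phys": cube(sifrel_struct * (phi - 1.0), "-", "sifrel_phys"),
            "et_true": cube(et_true, "W m-2", "et_true"),
            "et_struct": cube(et_struct, "W m-2", "et_struct"),
            "et_phys": cube(et_struct * (phi - 1.0), "W m-2", "et_phys"),
            "vodratio_struct": cube(np.ones_like(phi), "-", "vodratio_struct"),
            "vodratio_phys": cube(
                -config.vod_delta * (1.0 - phi), "-", "vodratio_phys"
            ),
        }
    )
    return obs, truth


def generate_ensemble(config: SimConfig) -> SimBundle:
    """Full forcing + observations + truth, deterministic in the seed."""
    bundle = generate_met(config)
    obs, truth = generate_observations(bundle, config)
    bundle.obs = obs
    bundle.truth = truth
    return bundle


def null_physiology(config: SimConfig) -> SimConfig:
    """Variant of a configuration with the physiological signal switched off."""
    return replace(config, phys_sensitivity=(0.0, 0.0))
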