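"""End-to-end orchestration of the analysis on a synthetic ensemble.

Chains the stages in the order the method runs: daily observation streams
-> 16-day moving-window aggregation to 8-daily -> SIFrel / SSEB-ET / VOD
ratio -> climatology + LOWESS anomalies -> growing season and cell masks
-> drought selection and peaks -> two-model decomposition.  Used by the
command-line interface and the acceptance script; every step is a thin
call into the corresponding module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from . import drought, preprocess, sseb
from .cubes import CELL, TIME
from .disentangle import DecompositionConfig, decompose, vod_ratio
from .synthetic_data import SimBundle, SimConfig

TARGETS = ("sifrel", "et", "vodratio")


@dataclass
class PipelineData:
    static: preprocess.StaticFields
    aridity: pd.Series  # recomputed from the generated met record
    mask: pd.Series
    growing: xr.DataArray  # 8-daily in-season flags
    sif_clim: xr.DataArray
    sm8: xr.DataArray
    sm_anom: xr.Dataset
    targets: dict = field(default_factory=dict)  # name -> AnomalyCube Dataset
    structures: dict = field(default_factory=dict)
    met: dict = field(default_factory=dict)  # predictor name -> anomaly cube


def prepare(bundle: SimBundle, window_frac: float = 0.4) -> PipelineData:
    """Aggregate, derive target streams and compute all anomaly cubes."""
    obs = bundle.obs
    agg = preprocess.aggregate_8daily

    # observation streams at 8-daily
    lai8 = agg(obs["lai"])
    nirv8 = agg(obs["nirv"])
    sif8 = agg(obs["sif"])
    sifrel8 = agg(obs["sif"] / obs["nir_radiance"])
    vodratio8 = agg(vod_ratio(obs["vod_day"], obs["vod_night"]))

    # SSEB ET from midday LST and the daily met summaries
    summ = bundle.summaries
    ga = sseb.mix_ga_static(bundle.static).values[:, None]
    et_daily_vals = sseb.estimate_et(
        obs["lst_midday"].values,
        summ["tamax"].values,
        summ["rsmax"].values,
        summ["rnmean"].values,
        ga,
    )
    et_daily = obs["lst_midday"].copy(data=et_daily_vals)
    et_daily.name = "et"
    et_daily.attrs["units"] = "W m-2"
    et8 = agg(et_daily)

    # met predictors at 8-daily
    md = bundle.met_daily
    sm_daily = preprocess.soil_moisture_1m(
        md["sm_layer1"], md["sm_layer2"], md["sm_layer3"]
    )
    ta8 = agg(md["ta"])
    met8 = {
        "ta": ta8,
        "swnet": agg(md["swnet"]),
        "vpd": agg(md["vpd"]),
        "sm": agg(sm_daily),
        "precip": agg(md["precip"]),
    }
    sm8 = met8["sm"]

    # anomalies
    data = PipelineData(
        static=bundle.static,
        aridity=pd.Series(
            preprocess.aridity_index(
                np.maximum(bundle.met_daily["rn"].values, 0.0).mean(axis=1),
                bundle.met_daily["precip"].values.mean(axis=1),
            ),
            index=bundle.static.table.index,
            name="aridity",
        ),
        mask=None,
        growing=None,
        sif_clim=preprocess.monthly_climatology(sif8),
        sm8=sm8,
        sm_anom=preprocess.compute_anomalies(sm8, window_frac),
    )
    data.targets = {
        "sifrel": preprocess.compute_anomalies(sifrel8, window_frac),
        "et": preprocess.compute_anomalies(et8, window_frac),
        "vodratio": preprocess.compute_anomalies(vodratio8, window_frac),
    }
    data.structures = {
        "lai": preprocess.compute_anomalies(lai8, window_frac),
        "nirv": preprocess.compute_anomalies(nirv8, window_frac),
    }
    data.met = {k: preprocess.compute_anomalies(v, window_frac) for k, v in met8.items()}

    data.growing = drought.growing_season_mask(ta8, data.sif_clim)
    data.mask = preprocess.build_mask(
        bundle.static,
        vod_day=agg(obs["vod_day"]),
        vod_night=agg(obs["vod_night"]),
        growing_mask=data.growing,
    )
    return data


def detect(data: PipelineData, bundle: SimBundle, config: SimConfig,
           variant: str = "absolute"):
    """Severe-drought cell selection and the per-cell event table."""
    selection = drought.select_drought_cells(bundle.sm_monthly, config.study_years)
    events = drought.detect_events(
        data.sm8,
        data.sm_anom["anomaly"],
        data.growing,
        selection,
        bundle.sm_monthly,
        variant=variant,
    )
    return selection, events


def met_anomaly_set(data: PipelineData) -> xr.Dataset:
    return xr.Dataset({k: v["anomaly"] for k, v in data.met.items()})


def decompose_target(
    data: PipelineData,
    target: str,
    cfg: DecompositionConfig | None = None,
    cells=None,
    keep_models: bool = False,
) -> xr.Dataset:
    """Two-model decomposition for one stream over the masked cells."""
    if cfg is None:
        cfg = DecompositionConfig(target=target)
    if cells is None:
        cells = data.mask.index[data.mask].values
    struct = data.structures[cfg.structure_proxy]["anomaly"]
    return decompose(
        data.targets[target]["anomaly"],
        struct,
        met_anomaly_set(data),
        data.growing,
        cfg,
        cells=cells,
        keep_models=keep_models,
    )


def run(config: SimConfig, targets=TARGETS, decomp_cfg: DecompositionConfig | None = None,
        cells=None):
    """Generate an ensemble and run the full analysis; returns a dict."""
    from .synthetic_data import generate_ensemble

    bundle = generate_ensemble(config)
    data = prepare(bundle)
    selection, events = detect(data, bundle, config)
    decomps = {}
    for t in targets:
        cfg = decomp_cfg or DecompositionConfig(target=t, seed=config.seed)
        cfg = DecompositionConfig(**{**cfg.__dict__, "target": t})
        decomps[t] = decompose_target(data, t, cfg, cells=cells)
    return {
        "bundle": bundle,
        "data": data,
        "selection": selection,
        "events": events,
        "decomps": decomps,
    }
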