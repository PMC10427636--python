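"""Spatial attribution of drought-window physiological anomalies.

Explains the across-cell variability of the mean physiological anomaly with
static drivers (aridity, tree cover), drought duration and window-averaged
hydro-meteorological anomalies, using a bagged-tree model ranked by mean
absolute Shapley value (with a 5-fold cross-validation R^2 for model skill)
and, as a collinearity-robust alternative, absolute Spearman correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from ._shapley import shapley_values
from .cubes import CELL

log = logging.getLogger(__name__)

DEV_WINDOW = (-12, 0)  # steps relative to the peak, inclusive
RECOV_WINDOW = (1, 11)


@dataclass
class ImportanceResult:
    table: pd.DataFrame  # per driver: importance, rank
    cv_r2: float | None
    method: str

    def top(self, k: int = 5) -> list[str]:
        return list(self.table.sort_values("rank").index[:k])


def _window_mean(cube: xr.DataArray, peaks: pd.Series, window) -> pd.Series:
    lo_off, hi_off = window
    cell_ids = cube[CELL].values
    vals = cube.values
    out = {}
    for c, p in peaks.items():
        if c not in cell_ids:
            continue
        i = int(np.where(cell_ids == c)[0][0])
        lo, hi = max(p + lo_off, 0), min(p + hi_off + 1, vals.shape[1])
        win = vals[i, lo:hi]
        out[c] = float(np.nanmean(win)) if np.isfinite(win).any() else np.nan
    return pd.Series(out)


def build_driver_table(
    decomp: xr.Dataset,
    events: pd.DataFrame,
    met_anoms: xr.Dataset,
    static,
    phase: str = "development",
    met_vars=("ta", "swnet", "vpd", "sm", "precip"),
) -> pd.DataFrame:
    """One row per kept cell: response (drought-window mean physiological
    anomaly) plus drivers.  Development rows carry development-window met
    anomalies; recovery rows carry both windows and both durations.
    Rows with any missing driver are dropped (logged)."""
    if phase not in ("development", "recovery"):
        raise ValueError("phase must be development or recovery")
    kept_cells = decomp[CELL].values[decomp["kept"].values]
    peaks = events.loc[events.index.intersection(kept_cells), "peak_step"]
    window = DEV_WINDOW if phase == "development" else RECOV_WINDOW
    physio = decomp["physiological"]
    resp = _window_mean(physio, peaks, window)
    t = static.table
    df = pd.DataFrame({"response": resp})
    df["aridity"] = t.loc[df.index, "aridity"]
    df["tree_frac"] = t.loc[df.index, "tree_frac"]
    df["dev_duration"] = events.loc[df.index, "dev_duration"].astype(float)
    if phase == "recovery":
        df["recov_duration"] = events.loc[df.index, "recov_duration"].astype(float)
    for v in met_vars:
        df[f"{v}_dev"] = _window_mean(met_anoms[v], peaks, DEV_WINDOW)
        if phase == "recovery":
            df[f"{v}_recov"] = _window_mean(met_anoms[v], peaks, RECOV_WINDOW)
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        log.info("build_driver_table: dropped %d incomplete rows", n0 - len(df))
    return df


def shapley_importance(
    table: pd.DataFrame,
    seed: int = 0,
    n_trees: int = 200,
    min_rows: int = 50,
    n_folds: int = 5,
    background_size: int = 30,
) -> ImportanceResult:
    """Drivers ranked by mean |Shapley| in a bagged-tree model across cells.

    Cross-validation R^2 is computed on pooled out-of-fold predictions
    (5 folds, seeded).  Refuses tables with fewer than ``min_rows`` rows.
    """
    if len(table) < min_rows:
        raise ValueError(f"attribution needs >= {min_rows} rows, got {len(table)}")
    X = table.drop(columns="response").values
    y = table["response"].values
    names = [c for c in table.columns if c != "response"]
    rng = np.random.default_rng(seed)

    oof = np.full(y.size, np.nan)
    for tr, te in KFold(n_folds, shuffle=True, random_state=seed).split(X):
        rf = RandomForestRegressor(
            n_estimators=n_trees, min_samples_leaf=5, random_state=seed, n_jobs=1
        )
        rf.fit(X[tr], y[tr])
        oof[te] = rf.predict(X[te])
    cv_r2 = 1.0 - np.sum((y - oof) ** 2) / np.sum((y - y.mean()) ** 2)

    rf = RandomForestRegressor(
        n_estimators=n_trees, min_samples_leaf=5, random_state=seed, n_jobs=1
    )
    rf.fit(X, y)
    bg = X[rng.choice(len(X), size=min(background_size, len(X)), replace=False)]
    phi, _ = shapley_values(rf.predict, X, bg, rng=rng)
    imp = np.abs(phi).mean(axis=0)
    tab = pd.DataFrame({"importance": imp}, index=pd.Index(names, name="driver"))
    tab["rank"] = tab["importance"].rank(ascending=False, method="first").astype(int)
    return ImportanceResult(tab, float(cv_r2), "shapley")


def spearman_importance(table: pd.DataFrame, min_rows: int = 10) -> ImportanceResult:
    """Per-driver |Spearman rho| with the response; constant drivers rank last."""
    if len(table) < min_rows:
        raise ValueError(f"need >= {min_rows} rows, got {len(table)}")
    y = table["response"].values
    rows = {}
    for c in table.columns:
        if c == "response":
            continue
        x = table[c].values
        if np.nanstd(x) == 0:
            rows[c] = np.nan
            log.info("spearman_importance: driver %s constant", c)
            continue
        rho, _ = spearmanr(x, y)
        rows[c] = abs(rho)
    tab = pd.DataFrame({"importance": pd.Series(rows)})
    tab.index.name = "driver"
    tab["rank"] = (
        tab["importance"].fillna(-np.inf).rank(ascending=False, method="first").astype(int)
    )
    return ImportanceResult(tab, None, "spearman")


def top5_overlap(a: ImportanceResult, b: ImportanceResult, k: int = 5) -> int:
    """Number of drivers shared between the two methods' top-k rankings."""
    return len(set(a.top(k)) & set(b.top(k)))
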