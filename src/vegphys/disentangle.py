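"""Two-model decomposition of vegetation anomalies into structure + physiology.

For each grid cell and target stream (relative SIF, ET, or the midday/
midnight VOD ratio) two bagged-tree regressions are fitted on growing-season
anomalies:

* a structure-only model predicting the target from the structure proxy
  (LAI by default, NIRv as a variant).  Predictions for each scheduled
  leave-out block come from a model trained with that block excluded, so
  drought-period predictions never see drought-period data and represent
  what structure alone would imply;
* a full model on structure plus hydro-meteorological anomalies, trained on
  the whole growing season; its out-of-bag R^2 screens cells (<= threshold
  dropped).

The physiological component is full-model minus structure-only prediction
at every step — by construction the decomposition identity
``full = structural + physiological`` is exact.  Two variance-decomposition
variants are provided as cross-checks: a multiple linear regression whose
met-term sum is read as physiology, and Shapley contributions of the met
predictors in the full model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.ensemble import RandomForestRegressor

from ._shapley import shapley_values
from .cubes import CELL, TIME

log = logging.getLogger(__name__)

MET_PREDICTORS = ("ta", "swnet", "vpd", "sm", "precip")


@dataclass
class DecompositionConfig:
    target: str = "sifrel"  # sifrel | et | vodratio
    structure_proxy: str = "lai"  # lai | nirv
    leaveout_steps: int = 24  # 192 days; 12 and 6 as robustness variants
    oob_threshold: float = 0.0  # cells with OOB R^2 <= threshold are dropped
    met_predictors: tuple = MET_PREDICTORS
    n_trees: int = 150
    min_leaf: int = 5
    seed: int = 0
    full_model_leaveout: bool = False  # default: full model sees all data
    min_train_steps: int = 30

    def __post_init__(self):
        if self.oob_threshold not in (0.0, 0.1, 0.2):
            raise ValueError("oob_threshold must be one of 0, 0.1, 0.2")
        if self.leaveout_steps <= 0:
            raise ValueError("leaveout_steps must be positive")


def vod_ratio(day: xr.DataArray, night: xr.DataArray) -> xr.DataArray:
    """Elementwise midday/midnight VOD; non-positive midnight VOD -> missing."""
    d = day.values
    n = night.values
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(n > 0, d / n, np.nan)
    out = day.copy(data=r)
    out.name = "vod_ratio"
    out.attrs = {"units": "-"}
    return out


def _blocks(n_steps: int, size: int) -> list[np.ndarray]:
    """Leave-out blocks tiling the record from its start."""
    return [np.arange(lo, min(lo + size, n_steps)) for lo in range(0, n_steps, size)]


def _forest(cfg: DecompositionConfig, seed: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=cfg.n_trees,
        min_samples_leaf=cfg.min_leaf,
        random_state=seed,
        bootstrap=True,
        n_jobs=1,
    )


def _cell_seed(cfg: DecompositionConfig, cell: int, salt: int = 0) -> int:
    return (cfg.seed * 1_000_003 + cell * 97 + salt) % (2**31 - 1)


def fit_structure_model(
    y: np.ndarray, x_struct: np.ndarray, train_ok: np.ndarray, cfg: DecompositionConfig,
    cell: int = 0,
) -> np.ndarray:
    """Leave-out predictions of the structure-only model over all steps.

    ``train_ok`` flags steps usable for training (growing season, target and
    predictor valid).  Returns predictions wherever the predictor is valid,
    NaN elsewhere; None if no block leaves enough training data.
    """
    n_steps = y.size
    pred = np.full(n_steps, np.nan)
    pred_ok = np.isfinite(x_struct)
    X = x_struct.reshape(-1, 1)
    for b, block in enumerate(_blocks(n_steps, cfg.leaveout_steps)):
        out_mask = np.zeros(n_steps, dtype=bool)
        out_mask[block] = True
        train = train_ok & ~out_mask
        target_steps = out_mask & pred_ok
        if not target_steps.any():
            continue
        if train.sum() < cfg.min_train_steps:
            log.info("fit_structure_model: cell %d block %d short of data", cell, b)
            return None
        rf = _forest(cfg, _cell_seed(cfg, cell, salt=b + 1))
        rf.fit(X[train], y[train])
        pred[target_steps] = rf.predict(X[target_steps])
    return pred


def fit_full_model(
    y: np.ndarray, X_full: np.ndarray, train_ok: np.ndarray, cfg: DecompositionConfig,
    cell: int = 0,
):
    """Full model (structure + met) trained on the whole growing season.

    Returns (predictions over all predictor-valid steps, OOB R^2, fitted
    forest, training mask).  OOB R^2 = 1 - SSE_oob / SST on the training
    steps.  When ``full_model_leaveout`` is set the predictions are produced
    with the same block scheduling as the structure model (toggle for the
    ambiguity in whether drought predictions should also be held out).
    """
    n_steps = y.size
    pred_ok = np.isfinite(X_full).all(axis=1)
    if train_ok.sum() < cfg.min_train_steps:
        return None
    rf = _forest(cfg, _cell_seed(cfg, cell))
    rf.set_params(oob_score=True)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # "some inputs do not have OOB scores"
        rf.fit(X_full[train_ok], y[train_ok])
    y_tr = y[train_ok]
    oob_pred = rf.oob_prediction_
    have = np.isfinite(oob_pred)
    sse = float(np.sum((y_tr[have] - oob_pred[have]) ** 2))
    sst = float(np.sum((y_tr[have] - y_tr[have].mean()) ** 2))
    oob_r2 = 1.0 - sse / sst if sst > 0 else np.nan

    pred = np.full(n_steps, np.nan)
    if cfg.full_model_leaveout:
        for b, block in enumerate(_blocks(n_steps, cfg.leaveout_steps)):
            out_mask = np.zeros(n_steps, dtype=bool)
            out_mask[block] = True
            train = train_ok & ~out_mask
            steps = out_mask & pred_ok
            if not steps.any():
                continue
            if train.sum() < cfg.min_train_steps:
                return None
            rf_b = _forest(cfg, _cell_seed(cfg, cell, salt=1000 + b))
            rf_b.fit(X_full[train], y[train])
            pred[steps] = rf_b.predict(X_full[steps])
    else:
        pred[pred_ok] = rf.predict(X_full[pred_ok])
    return pred, oob_r2, rf, train_ok


def physiological_component(full_pred: np.ndarray, struct_pred: np.ndarray) -> np.ndarray:
    """Physiology = full-model minus structure-only prediction, per step."""
    return full_pred - struct_pred


def decompose(
    target_anom: xr.DataArray,
    struct_anom: xr.DataArray,
    met_anoms: xr.Dataset,
    growing_mask: xr.DataArray,
    cfg: DecompositionConfig,
    cells=None,
    keep_models: bool = False,
) -> xr.Dataset:
    """Per-cell two-model decomposition over an ensemble of cells.

    Returns a Dataset with ``total`` (the target anomalies), ``structural``,
    ``full`` and ``physiological`` (cell x time) plus per-cell ``oob_r2``
    and ``kept``.  Cells where either model cannot be trained are dropped.
    """
    cell_ids = target_anom[CELL].values
    if cells is None:
        cells = cell_ids
    met = [met_anoms[v].values for v in cfg.met_predictors]
    y_all = target_anom.values
    xs_all = struct_anom.values
    season = growing_mask.values.astype(bool)
    n_t = y_all.shape[1]

    keep_idx, oob_scores = [], []
    struct_out = np.full((len(cells), n_t), np.nan)
    full_out = np.full((len(cells), n_t), np.nan)
    models = {}
    for k, c in enumerate(cells):
        i = int(np.where(cell_ids == c)[0][0])
        y = y_all[i]
        xs = xs_all[i]
        X_full = np.column_stack([xs] + [m[i] for m in met])
        train_ok = season[i] & np.isfinite(y) & np.isfinite(X_full).all(axis=1)
        sp = fit_structure_model(y, xs, train_ok, cfg, cell=int(c))
        if sp is None:
            log.info("decompose: dropping cell %s (structure model)", c)
            continue
        res = fit_full_model(y, X_full, train_ok, cfg, cell=int(c))
        if res is None:
            log.info("decompose: dropping cell %s (full model)", c)
            continue
        fp, oob_r2, rf, train_mask = res
        struct_out[k] = sp
        full_out[k] = fp
        keep_idx.append(k)
        oob_scores.append(oob_r2)
        if keep_models:
            models[int(c)] = (rf, X_full, train_mask)

    cells = np.asarray(cells)[keep_idx]
    struct_out = struct_out[keep_idx]
    full_out = full_out[keep_idx]
    oob = np.asarray(oob_scores)
    kept = np.isfinite(oob) & (oob > cfg.oob_threshold)

    time = target_anom[TIME].values
    coords = {CELL: cells, TIME: time}
    ds = xr.Dataset(
        {
            "total": ((CELL, TIME), y_all[[int(np.where(cell_ids == c)[0][0]) for c in cells]]),
            "structural": ((CELL, TIME), struct_out),
            "full": ((CELL, TIME), full_out),
            "physiological": ((CELL, TIME), full_out - struct_out),
            "oob_r2": ((CELL,), oob),
            "kept": ((CELL,), kept),
        },
        coords=coords,
    )
    ds.attrs["target"] = cfg.target
    if keep_models:
        ds.attrs["_models"] = models  # in-memory only; not serializable
    return ds


# ---------------------------------------------------------------------------
# variance-decomposition variants
# ---------------------------------------------------------------------------

def mlr_decomposition(
    y: np.ndarray, x_struct: np.ndarray, X_met: np.ndarray, train_ok: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary least squares on structure + met; physiology is the sum of
    the fitted met terms evaluated at each step's met values.

    Collinear columns (detected by pivoted QR on the training design) are
    dropped with a log entry.  Returns (physiological series, met
    coefficients with NaN for dropped columns).
    """
    n_met = X_met.shape[1]
    design = np.column_stack([np.ones_like(y), x_struct, X_met])
    A = design[train_ok]
    from scipy.linalg import qr

    _, r, piv = qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps
    keep_cols = np.sort(piv[: int((diag > tol).sum())])
    if keep_cols.size < design.shape[1]:
        log.info("mlr_decomposition: dropped %d collinear columns",
                 design.shape[1] - keep_cols.size)
    beta = np.zeros(design.shape[1])
    coef, *_ = np.linalg.lstsq(A[:, keep_cols], y[train_ok], rcond=None)
    beta[keep_cols] = coef
    met_beta = beta[2:]
    physio = X_met @ met_beta
    met_beta_out = met_beta.copy()
    dropped = np.setdiff1d(np.arange(2, 2 + n_met), keep_cols)
    met_beta_out[dropped - 2] = np.nan
    return physio, met_beta_out


def shapley_decomposition(
    model: RandomForestRegressor,
    X_full: np.ndarray,
    steps: np.ndarray,
    background: np.ndarray,
    n_met: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Physiology at the given steps as the summed Shapley contributions of
    the met predictors (all columns after the structure proxy).

    Returns (physiological values at `steps`, full contribution matrix,
    base value); base + contributions.sum(1) equals the model prediction
    row-wise (Shapley efficiency).
    """
    X = X_full[steps]
    phi, base = shapley_values(
        model.predict, X, background, rng=np.random.default_rng(seed)
    )
    start = 1  # column 0 is the structure proxy
    physio = phi[:, start:].sum(axis=1)
    return physio, phi, base


def drought_window_median(series: xr.DataArray, peaks: pd.Series, pre: int = 12,
                          post: int = 11) -> pd.Series:
    """Median of a (cell x time) series over each cell's drought window."""
    cell_ids = series[CELL].values
    vals = series.values
    out = {}
    for c, p in peaks.items():
        if c not in cell_ids:
            continue
        i = int(np.where(cell_ids == c)[0][0])
        lo, hi = max(p - pre, 0), min(p + post + 1, vals.shape[1])
        win = vals[i, lo:hi]
        out[c] = np.nanmedian(win) if np.isfinite(win).any() else np.nan
    return pd.Series(out)
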