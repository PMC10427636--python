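"""Two-model decomposition, MLR and Shapley variants, recovery properties."""

import numpy as np
import pandas as pd
import pytest

from vegphys import pipeline
from vegphys.disentangle import (
    DecompositionConfig,
    _blocks,
    decompose,
    fit_full_model,
    fit_structure_model,
    mlr_decomposition,
    shapley_decomposition,
    vod_ratio,
)

from conftest import make_8daily


class TestVodRatio:
    def test_identity_and_division(self):
        day = make_8daily(np.array([[0.5, 0.55, 0.5]]))
        night = make_8daily(np.array([[0.5, 0.50, -0.1]]))
        r = vod_ratio(day, night)
        assert r.values[0, 0] == pytest.approx(1.0)
        assert r.values[0, 1] == pytest.approx(1.1)
        assert np.isnan(r.values[0, 2])


def test_blocks_tile_record():
    blocks = _blocks(50, 24)
    assert [b[0] for b in blocks] == [0, 24, 48]
    assert sum(len(b) for b in blocks) == 50


def _series(n=230, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    return x, rng


class TestStructureModel:
    def test_recovers_known_relation(self):
        x, rng = _series(n=500)  # dense enough that 5-point leaves resolve the line
        y = 2.0 * x
        cfg = DecompositionConfig(seed=1)
        train = np.ones_like(y, dtype=bool)
        pred = fit_structure_model(y, x, train, cfg)
        rmse = np.sqrt(np.nanmean((pred - y) ** 2))
        assert rmse < 0.1 * np.std(y)

    def test_no_signal_gives_no_skill(self):
        x, rng = _series(seed=3)
        y = rng.normal(size=x.size)
        cfg = DecompositionConfig(seed=1)
        pred = fit_structure_model(y, x, np.ones_like(y, dtype=bool), cfg)
        ss_res = np.nansum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot < 0.2

    def test_deterministic_in_seed(self):
        x, _ = _series(seed=5)
        y = x**2
        cfg = DecompositionConfig(seed=9)
        train = np.ones_like(y, dtype=bool)
        p1 = fit_structure_model(y, x, train, cfg, cell=3)
        p2 = fit_structure_model(y, x, train, cfg, cell=3)
        np.testing.assert_array_equal(p1, p2)

    def test_insufficient_data_returns_none(self):
        x, _ = _series(n=40)
        y = x.copy()
        cfg = DecompositionConfig(seed=1, min_train_steps=35)
        assert fit_structure_model(y, x, np.ones_like(y, bool), cfg) is None


class TestFullModel:
    def test_oob_high_on_clean_signal(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(230, 4))
        y = X[:, 0] + 0.5 * X[:, 1] - 0.8 * X[:, 2]
        cfg = DecompositionConfig(seed=1)
        pred, oob, rf, _ = fit_full_model(y, X, np.ones(230, bool), cfg)
        assert oob > 0.8

    def test_oob_near_zero_on_noise(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(230, 4))
        y = rng.normal(size=230)
        cfg = DecompositionConfig(seed=1)
        _, oob, _, _ = fit_full_model(y, X, np.ones(230, bool), cfg)
        assert oob < 0.15


@pytest.fixture(scope="module")
def small_decomp(small_data, small_events, small_config):
    """Decomposition of SIFrel on a handful of drought cells, models kept."""
    _, events = small_events
    cells = [c for c in small_config.drought_cells
             if small_data.mask.get(c, False) and c in events.index][:8]
    cfg = DecompositionConfig(target="sifrel", seed=small_config.seed)
    dec = pipeline.decompose_target(small_data, "sifrel", cfg, cells=cells,
                                    keep_models=True)
    return dec, cfg, events


class TestDecomposition:
    def test_identity_exact(self, small_decomp):
        dec, _, _ = small_decomp
        diff = dec["physiological"].values - (
            dec["full"].values - dec["structural"].values
        )
        assert np.nanmax(np.abs(diff)) == 0.0

    def test_kept_flag_vs_threshold(self, small_decomp):
        dec, cfg, _ = small_decomp
        oob = dec["oob_r2"].values
        np.testing.assert_array_equal(
            dec["kept"].values, np.isfinite(oob) & (oob > cfg.oob_threshold)
        )

    def test_threshold_monotonicity(self, small_decomp):
        dec, _, _ = small_decomp
        oob = dec["oob_r2"].values
        kept0 = set(dec.cell.values[oob > 0.0])
        kept2 = set(dec.cell.values[oob > 0.2])
        assert kept2 <= kept0

    def test_recovers_truth_in_drought_window(self, small_decomp, small_bundle):
        from vegphys.preprocess import aggregate_8daily

        dec, _, events = small_decomp
        truth8 = aggregate_8daily(small_bundle.truth["sifrel_phys"])
        rec_all, tru_all = [], []
        for k, c in enumerate(dec.cell.values):
            p = int(events.loc[c, "peak_step"])
            rec = dec["physiological"].values[k, p - 12 : p + 12]
            j = int(np.where(truth8.cell.values == c)[0][0])
            tru = truth8.values[j, p - 12 : p + 12]
            ok = np.isfinite(rec) & np.isfinite(tru)
            rec_all.extend(rec[ok])
            tru_all.extend(tru[ok])
        r = np.corrcoef(rec_all, tru_all)[0, 1]
        assert r > 0.6

    def test_leaveout_window_robustness(self, small_data, small_events, small_config,
                                        small_decomp):
        """Sign of the drought-window median agrees across 24/12/6-step blocks."""
        from vegphys.disentangle import drought_window_median

        dec24, _, events = small_decomp
        cells = list(dec24.cell.values)
        medians = {}
        for steps in (24, 12, 6):
            if steps == 24:
                dec = dec24
            else:
                cfg = DecompositionConfig(target="sifrel", seed=small_config.seed,
                                          leaveout_steps=steps)
                dec = pipeline.decompose_target(small_data, "sifrel", cfg, cells=cells)
            medians[steps] = drought_window_median(
                dec["physiological"], events.loc[cells, "peak_step"]
            )
        base = np.sign(medians[24])
        for steps in (12, 6):
            agree = (np.sign(medians[steps].loc[base.index]) == base).mean()
            assert agree >= 0.8


class TestMLR:
    def test_recovers_planted_met_contribution(self):
        rng = np.random.default_rng(11)
        n = 600
        lai = rng.normal(size=n)
        vpd = rng.normal(size=n)
        other = rng.normal(size=(n, 2))
        signal = 0.5 * lai + 0.3 * vpd
        y = signal + 0.1 * np.std(signal) * rng.normal(size=n)
        X_met = np.column_stack([vpd, other])
        physio, beta = mlr_decomposition(y, lai, X_met, np.ones(n, bool))
        assert beta[0] == pytest.approx(0.3, rel=0.05)
        ref = 0.3 * vpd
        assert np.sqrt(np.mean((physio - ref) ** 2)) < 0.1 * np.std(ref)

    def test_zero_met_coefficients(self):
        rng = np.random.default_rng(12)
        n = 400
        lai = rng.normal(size=n)
        X_met = rng.normal(size=(n, 3))
        y = 0.7 * lai
        physio, beta = mlr_decomposition(y, lai, X_met, np.ones(n, bool))
        assert np.nanmax(np.abs(beta)) < 1e-10
        assert np.max(np.abs(physio)) < 1e-9

    def test_collinear_column_dropped(self):
        rng = np.random.default_rng(13)
        n = 200
        lai = rng.normal(size=n)
        v = rng.normal(size=n)
        X_met = np.column_stack([v, 2.0 * v])  # exactly collinear
        y = 0.5 * lai + 0.3 * v + 0.01 * rng.normal(size=n)
        physio, beta = mlr_decomposition(y, lai, X_met, np.ones(n, bool))
        assert np.isnan(beta).sum() == 1

    def test_sign_agreement_with_two_model_method(self, small_data, small_events,
                                                  small_decomp, small_config):
        """On the synthetic ensemble the MLR physiological component agrees in
        sign with the two-forest method on most drought steps."""
        dec, cfg, events = small_decomp
        met = pipeline.met_anomaly_set(small_data)
        struct = small_data.structures["lai"]["anomaly"]
        target = small_data.targets["sifrel"]["anomaly"]
        season = small_data.growing.values.astype(bool)
        agree = []
        cell_ids = target.cell.values
        for k, c in enumerate(dec.cell.values):
            i = int(np.where(cell_ids == c)[0][0])
            y = target.values[i]
            xs = struct.values[i]
            X_met = np.column_stack([met[v].values[i] for v in cfg.met_predictors])
            ok = season[i] & np.isfinite(y) & np.isfinite(xs) & np.isfinite(X_met).all(axis=1)
            physio, _ = mlr_decomposition(y, xs, X_met, ok)
            p = int(events.loc[c, "peak_step"])
            win = slice(p - 12, p + 12)
            rf_phys = dec["physiological"].values[k, win]
            both = np.isfinite(rf_phys) & ok[win]
            if both.sum() > 5:
                agree.append(
                    (np.sign(rf_phys[both]) == np.sign(physio[win][both])).mean()
                )
        assert np.mean(agree) > 0.7


class TestShapleyVariant:
    def test_efficiency_and_met_sum(self, small_decomp):
        dec, cfg, events = small_decomp
        models = dec.attrs["_models"]
        c = int(dec.cell.values[0])
        rf, X_full, train_mask = models[c]
        p = int(events.loc[c, "peak_step"])
        steps = np.arange(p - 4, p + 4)
        steps = steps[np.isfinite(X_full[steps]).all(axis=1)]
        bg = X_full[train_mask][:40]
        physio, phi, base = shapley_decomposition(rf, X_full, steps, bg, seed=0)
        np.testing.assert_allclose(
            base + phi.sum(axis=1), rf.predict(X_full[steps]), atol=1e-6
        )
        np.testing.assert_allclose(physio, phi[:, 1:].sum(axis=1), atol=1e-12)

    def test_structure_only_target_gives_zero_met_contribution(self):
        from sklearn.ensemble import RandomForestRegressor

        rng = np.random.default_rng(21)
        X = rng.normal(size=(300, 4))
        y = np.sin(X[:, 0])  # depends on the structure column only
        rf = RandomForestRegressor(n_estimators=100, random_state=0).fit(X, y)
        physio, phi, _ = shapley_decomposition(
            rf, X, np.arange(10), X[:50], seed=0
        )
        assert np.max(np.abs(physio)) < 0.1 * np.std(y)

    def test_sign_agreement_with_two_model_method(self, small_decomp):
        dec, cfg, events = small_decomp
        models = dec.attrs["_models"]
        agree = []
        for k, c in enumerate(dec.cell.values[:4]):
            rf, X_full, train_mask = models[int(c)]
            p = int(events.loc[c, "peak_step"])
            steps = np.arange(max(p - 12, 0), p + 12)
            steps = steps[np.isfinite(X_full[steps]).all(axis=1)]
            bg = X_full[train_mask][:40]
            physio, _, _ = shapley_decomposition(rf, X_full, steps, bg, seed=0)
            rf_phys = dec["physiological"].values[k, steps]
            ok = np.isfinite(rf_phys)
            agree.append((np.sign(rf_phys[ok]) == np.sign(physio[ok])).mean())
        assert np.mean(agree) > 0.7
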