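"""Aggregation, climatology, detrending, masking and aridity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vegphys import preprocess
from vegphys.cubes import make_cube
from vegphys.preprocess import StaticFields

from conftest import make_8daily


def _daily(values, start="2020-01-01"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    time = pd.date_range(start, periods=values.shape[1], freq="D")
    return make_cube(values, time)


class TestAggregate8Daily:
    def test_constant_series(self):
        out = preprocess.aggregate_8daily(_daily(np.full(64, 5.0)))
        assert np.allclose(out.values, 5.0)

    def test_window_mean_1_to_16(self):
        out = preprocess.aggregate_8daily(_daily(np.arange(1.0, 17.0)))
        assert out.values[0, 0] == pytest.approx(8.5)

    def test_gap_rule_20_percent(self):
        base = np.arange(1.0, 17.0)
        four_missing = base.copy()
        four_missing[[2, 5, 9, 12]] = np.nan  # 25% gaps -> missing
        out = preprocess.aggregate_8daily(_daily(four_missing))
        assert np.isnan(out.values[0, 0])
        three_missing = base.copy()
        three_missing[[2, 5, 9]] = np.nan  # 18.75% -> kept
        out = preprocess.aggregate_8daily(_daily(three_missing))
        assert np.isfinite(out.values[0, 0])

    def test_overlap_stride(self):
        out = preprocess.aggregate_8daily(_daily(np.arange(80.0)))
        # windows [0..15], [8..23], ... -> means 7.5, 15.5, ...
        assert np.allclose(out.values[0], 7.5 + 8 * np.arange(out.sizes["time"]))

    def test_rejects_non_daily(self):
        with pytest.raises(ValueError):
            preprocess.aggregate_8daily(make_8daily(np.zeros((1, 20))))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_nanmean_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=40)
        vals[rng.random(40) < 0.1] = np.nan
        out = preprocess.aggregate_8daily(_daily(vals))
        for k in range(out.sizes["time"]):
            win = vals[8 * k : 8 * k + 16]
            if np.isnan(win).sum() / 16 > 0.2:
                assert np.isnan(out.values[0, k])
            else:
                assert out.values[0, k] == pytest.approx(np.nanmean(win))


class TestClimatology:
    def test_two_year_january_mean(self):
        cube = make_cube(
            np.array([[2.0, 4.0]]), pd.DatetimeIndex(["2019-01-10", "2020-01-10"])
        )
        clim = preprocess.monthly_climatology(cube)
        assert clim.sel(month=1).values[0] == pytest.approx(3.0)
        assert np.isnan(clim.sel(month=6).values[0])

    def test_all_missing_month_propagates(self):
        time = pd.date_range("2019-01-05", periods=92, freq="8D")
        vals = np.ones((1, 92))
        vals[0, time.month == 3] = np.nan
        anom = preprocess.compute_anomalies(make_cube(vals, time))
        months = pd.DatetimeIndex(anom["anomaly"].time.values).month
        assert np.isnan(anom["climatology"].sel(month=3).values[0])
        assert np.all(np.isnan(anom["anomaly"].values[0, months == 3]))

    def test_series_equal_to_climatology_gives_zero_anomaly(self):
        time = pd.date_range("2018-01-05", periods=184, freq="8D")
        clim_by_month = {m: float(m) for m in range(1, 13)}
        vals = np.array([[clim_by_month[m] for m in time.month]])
        anom = preprocess.compute_anomalies(make_cube(vals, time))
        assert np.nanmax(np.abs(anom["anomaly"].values)) < 1e-9


class TestLowess:
    def test_reproduces_line(self):
        time = pd.date_range("2018-01-05", periods=100, freq="8D")
        y = 0.3 * np.arange(100.0) - 4.0
        trend = preprocess.lowess_trend(make_cube(y[None, :], time))
        resid = y - trend.values[0]
        assert np.max(np.abs(resid)) < 1e-6 * (y.max() - y.min())

    def test_constant_series(self):
        time = pd.date_range("2018-01-05", periods=50, freq="8D")
        trend = preprocess.lowess_trend(make_cube(np.full((1, 50), 2.5), time))
        assert np.allclose(trend.values, 2.5)

    def test_spike_stays_in_residual(self):
        time = pd.date_range("2018-01-05", periods=100, freq="8D")
        x = np.arange(100.0)
        y = 0.2 * x
        y[50] += 10.0
        trend = preprocess.lowess_trend(make_cube(y[None, :], time))
        # independent least-squares line through the non-spike points
        line = np.polyval(np.polyfit(np.delete(x, 50), np.delete(y, 50), 1), 50.0)
        assert trend.values[0, 50] == pytest.approx(line, rel=0.1)
        assert (y[50] - trend.values[0, 50]) > 8.0  # spike preserved in residual

    def test_short_series_falls_back_to_mean(self):
        time = pd.date_range("2018-01-05", periods=20, freq="8D")
        vals = np.full((1, 20), np.nan)
        vals[0, :5] = [1.0, 2.0, 3.0, 4.0, 5.0]
        trend = preprocess.lowess_trend(make_cube(vals, time))
        assert np.allclose(trend.values, 3.0)


def test_anomaly_reconstruction_identity():
    rng = np.random.default_rng(3)
    time = pd.date_range("2017-01-05", periods=200, freq="8D")
    doy = time.dayofyear.values
    vals = 5 + 2 * np.sin(2 * np.pi * doy / 365) + 0.01 * np.arange(200)
    vals = vals[None, :] + 0.3 * rng.standard_normal((3, 200))
    anom = preprocess.compute_anomalies(make_cube(vals, time))
    recon = preprocess.anomaly_reconstruction(anom)
    ok = np.isfinite(recon)
    assert np.max(np.abs(recon[ok] - vals[ok])) < 1e-9


def test_climatology_plus_trend_gives_near_zero_anomaly():
    # the month-grouped climatology absorbs part of the trend, leaving a small
    # sawtooth; anomalies must still be an order below the signal scale
    time = pd.date_range("2017-01-05", periods=200, freq="8D")
    vals = (3 + np.sin(2 * np.pi * time.month.values / 12) + 0.02 * np.arange(200))[None, :]
    anom = preprocess.compute_anomalies(make_cube(vals, time))
    assert np.nanmedian(np.abs(anom["anomaly"].values)) < 0.1 * np.std(vals)


class TestSoilMoisture1m:
    def test_uniform_layers(self):
        l = make_8daily(np.full((1, 10), 0.3))
        out = preprocess.soil_moisture_1m(l, l, l)
        assert np.allclose(out.values, 0.3)

    def test_weighted_example(self):
        l1 = make_8daily(np.full((1, 4), 0.1))
        l2 = make_8daily(np.full((1, 4), 0.2))
        l3 = make_8daily(np.full((1, 4), 0.3))
        out = preprocess.soil_moisture_1m(l1, l2, l3)
        assert np.allclose(out.values, 0.265)

    def test_weights_sum_to_one(self):
        assert sum(preprocess.SOIL_LAYER_WEIGHTS) == pytest.approx(1.0)

    def test_missing_layer_propagates(self):
        l = make_8daily(np.full((1, 4), 0.3))
        lmiss = make_8daily(np.array([[0.3, np.nan, 0.3, 0.3]]))
        out = preprocess.soil_moisture_1m(l, lmiss, l)
        assert np.isnan(out.values[0, 1])


def _static(**overrides):
    base = dict(
        tree_frac=[0.4], shrub_frac=[0.2], grass_frac=[0.2], soil_frac=[0.2],
        irrigation_frac=[0.0], aridity=[1.0], lat=[40.0], lon=[10.0],
    )
    base.update({k: [v] for k, v in overrides.items()})
    return StaticFields(pd.DataFrame(base))


class TestMask:
    def test_sparse_cover_dropped(self):
        s = _static(tree_frac=0.01, shrub_frac=0.01, grass_frac=0.02, soil_frac=0.9)
        assert not preprocess.build_mask(s).iloc[0]

    def test_irrigation_dropped(self):
        assert not preprocess.build_mask(_static(irrigation_frac=0.12)).iloc[0]

    def test_vod_criterion_only_when_requested(self):
        day = make_8daily(np.full((1, 10), 0.61))
        night = make_8daily(np.full((1, 10), 0.60))
        s = _static()
        assert preprocess.build_mask(s).iloc[0]
        kept = preprocess.build_mask(s, vod_day=day, vod_night=night,
                                     apply_vod_criterion=True)
        assert not kept.iloc[0]

    def test_monotone_in_thresholds(self, small_bundle, small_data):
        from vegphys.preprocess import aggregate_8daily

        s = small_bundle.static
        loose = preprocess.build_mask(s, min_cover=0.05, max_irrigation=0.10)
        tight = preprocess.build_mask(s, min_cover=0.20, max_irrigation=0.02)
        assert set(tight.index[tight]) <= set(loose.index[loose])


class TestAridity:
    def test_boundary(self):
        p = 2.0  # mm/day
        rn = preprocess.MM_DAY_TO_WM2 * p
        assert preprocess.aridity_index(rn, p) == pytest.approx(1.0)

    def test_linear_in_radiation(self):
        a1 = preprocess.aridity_index(100.0, 2.0)
        a2 = preprocess.aridity_index(200.0, 2.0)
        assert a2 == pytest.approx(2 * a1)

    def test_unit_conversion_oracle(self):
        # lambda = 2.5e6 J/kg -> 1 mm/day = 2.5e6/86400 ~ 28.94 W/m2
        ai = preprocess.aridity_index(100.0, 2.0)
        assert ai == pytest.approx(100.0 / (2.0 * 2.5e6 / 86400.0), rel=1e-12)
        assert ai == pytest.approx(1.728, abs=1e-3)

    def test_zero_precip_flags_infinity(self):
        assert np.isposinf(preprocess.aridity_index(100.0, 0.0))


def test_dominance_classification():
    s = StaticFields(pd.DataFrame({
        "tree_frac": [0.6, 0.1], "shrub_frac": [0.1, 0.4], "grass_frac": [0.1, 0.4],
        "soil_frac": [0.2, 0.1], "irrigation_frac": [0, 0], "aridity": [1, 1],
        "lat": [0, 0], "lon": [0, 0],
    }))
    assert list(s.dominance()) == ["tree", "short"]
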