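import numpy as np
import pandas as pd
import pytest
import xarray as xr

from vegphys import SimConfig, generate_ensemble, pipeline
from vegphys.cubes import make_cube


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_cells=40, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_ensemble(small_config)


@pytest.fixture(scope="session")
def small_data(small_bundle):
    return pipeline.prepare(small_bundle)


@pytest.fixture(scope="session")
def small_events(small_data, small_bundle, small_config):
    selection, events = pipeline.detect(small_data, small_bundle, small_config)
    return selection, events


@pytest.fixture
def daily_cube():
    """One cell, 64 days of daily data, values 1..64."""
    time = pd.date_range("2020-01-01", periods=64, freq="D")
    return make_cube(np.arange(1.0, 65.0)[None, :], time)


def make_8daily(values, start="2018-01-05", cells=None):
    values = np.asarray(values, dtype=float)
    time = pd.date_range(start, periods=values.shape[1], freq="8D")
    return make_cube(values, time, cells=cells)
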