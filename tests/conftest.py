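"""Shared fixtures: small synthetic scenarios, generated at test time."""

from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest

from fluorocal import default_scenario
from fluorocal.cleaning import CleaningConfig
from fluorocal.io import EnvSeries, RawSensorSeries
from fluorocal.synthetic import simulate_sensor, simulate_truth


@pytest.fixture(scope="session")
def small_cfg():
    """Two tanks (one HN, one LN), 60 days, artifacts on."""
    return default_scenario(
        seed=7,
        tank_ids=("A1", "B1"),
        start=dt.date(2019, 5, 1),
        end=dt.date(2019, 6, 29),
    )


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return simulate_truth(small_cfg)


@pytest.fixture(scope="session")
def small_sensor(small_truth):
    return simulate_sensor(small_truth, "A1", "chla")


@pytest.fixture()
def cleaning_cfg():
    return CleaningConfig()


def make_series(values, start="2019-06-01 00:00", freq="5min", gain="X1",
                tank="A1", pigment="chla"):
    """A RawSensorSeries literal for unit tests."""
    idx = pd.date_range(start, periods=len(values), freq=freq)
    frame = pd.DataFrame({"value_mV": [float(v) for v in values], "gain": gain}, index=idx)
    return RawSensorSeries(sensor_id=f"{tank}_{pigment}", tank_id=tank,
                           pigment=pigment, frame=frame)


def night_par_for(series, value=1.0):
    """A PAR series marking every timestamp of ``series`` as night."""
    s = pd.Series(value, index=series.frame.index, name="par")
    return EnvSeries(kind="par", series=s, cadence=None)
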