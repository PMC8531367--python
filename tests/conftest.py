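import numpy as np
import pandas as pd
import pytest

from phenoclim import ClimateSimConfig, TrueModelConfig, simulate_climate, simulate_observations


@pytest.fixture(scope="session")
def small_climate():
    """5 sites x ~2.5 years of daily climate, no anomalous season."""
    return simulate_climate(
        ClimateSimConfig(
            n_sites=5,
            date_range=("2016-01-01", "2018-06-30"),
            seed=11,
            anomaly_interval=None,
        )
    )


@pytest.fixture(scope="session")
def small_observations(small_climate):
    """1200 observations from the default truth (no anomaly)."""
    return simulate_observations(
        small_climate,
        TrueModelConfig(anomaly_interval=None),
        n_obs=1200,
        seed=12,
    )


@pytest.fixture()
def constant_climate():
    """One site, constant tmean 15 °C (tmin 10, tmax 20), 1 mm/day, 200 days."""
    dates = pd.date_range("2020-01-01", periods=200, freq="D")
    return pd.DataFrame(
        {
            "site": "S000",
            "latitude": 34.0,
            "longitude": -116.0,
            "date": dates,
            "tmin": 10.0,
            "tmax": 20.0,
            "precip": 1.0,
        }
    )


def make_records(rows):
    """Observation table from (record_id, date, flower, whole_plant) tuples."""
    return pd.DataFrame(
        {
            "record_id": [r[0] for r in rows],
            "species": "test",
            "latitude": 34.0,
            "longitude": -116.0,
            "site": "S000",
            "date": pd.to_datetime([r[1] for r in rows]),
            "flower_annotation": [r[2] for r in rows],
            "whole_plant": [r[3] for r in rows],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
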