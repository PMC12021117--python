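import numpy as np
import pandas as pd
import pytest

from adaptrack import (
    OptimalStateSeries,
    SyntheticEnvConfig,
    build_kernel,
    synthetic_environment,
)
from adaptrack.series import HourlySeries


def hourly_index(n, start="2015-01-01"):
    return pd.date_range(start, periods=n, freq="h")


def make_series(values, cls=HourlySeries, start="2015-01-01", valid=None):
    values = np.asarray(values, dtype=float)
    return cls(hourly_index(len(values), start), values, valid)


def sinusoid(n_hours, period=24.0, amplitude=1.0, cls=HourlySeries):
    """A pure sinusoid A*sin(2*pi*t/period) on the hourly grid (t in hours)."""
    t = np.arange(n_hours, dtype=float)
    omega = 2 * np.pi / period
    return make_series(amplitude * np.sin(omega * t), cls=cls), omega, t


@pytest.fixture(scope="session")
def kernel():
    return build_kernel()  # b0 = 1/3 per hour, h = 1 h, M = 25


@pytest.fixture(scope="session")
def weather_env():
    """~90 days of synthetic irradiance with weather noise (seeded)."""
    return synthetic_environment(SyntheticEnvConfig(n_hours=24 * 90, seed=42))


@pytest.fixture(scope="session")
def clear_env():
    from adaptrack import generate_clear_sky

    return generate_clear_sky(SyntheticEnvConfig(n_hours=24 * 90, weather_sigma=0.0))
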