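import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_daily_series():
    """Deterministic 2-year daily series with a mild seasonal temperature."""
    dates = pd.date_range("2015-01-01", "2016-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    tmean = 10 + 9 * np.cos(2 * np.pi * (doy - 200) / 365.25)
    rng = np.random.default_rng(0)
    tmean = tmean + rng.normal(0, 2, len(dates))
    deaths = rng.poisson(30, len(dates)).astype(float)
    return pd.DataFrame({"date": dates, "deaths": deaths, "tmean": tmean})
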