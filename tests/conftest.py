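import numpy as np
import pytest

from pollenbeetle.weather import SiteClimate, WeatherSeries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def flat_site():
    """Degenerate climate: constant 10 degC every day."""
    return SiteClimate(
        annual_mean_temp=10.0,
        seasonal_amplitude=0.0,
        diurnal_range=0.0,
        day_to_day_sd=0.0,
        autocorrelation=0.0,
        latitude=52.0,
    )


def make_series(tmeans, year=0, diurnal_range=0.0, day_length=14.0):
    """Build a WeatherSeries with prescribed daily means for one year."""
    tmeans = np.asarray(tmeans, dtype=float)
    n = tmeans.size
    half = diurnal_range / 2.0
    return WeatherSeries(
        year=np.full(n, year, dtype=int),
        doy=np.arange(1, n + 1),
        tmin=tmeans - half,
        tmax=tmeans + half,
        day_length=np.full(n, day_length),
    )
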