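"""Synthetic daily weather, degree-day accumulation and seasonal triggers.

The simulator needs three climatic drivers per day: minimum/maximum air
temperature (from which a daily mean is formed) and day length.  Real runs of
this kind of model are usually driven by a stochastic weather generator
calibrated to station records; here a deliberately simple surrogate is used:
an annual sinusoid in the daily mean temperature plus stationary AR(1) noise,
with day length computed from latitude and calendar day by the standard
solar-declination formula.  Site presets differ only in annual mean,
seasonal amplitude and latitude, giving a maritime/continental contrast.

The insect and crop sub-models consume weather exclusively through
:func:`degree_days` (thermal time above a base temperature, 0 degC here) and
the two run-detection triggers: spring emergence fires when the daily mean
exceeds 9 degC on five consecutive days, autumn return when it falls below
12 degC on five consecutive days (searched after midsummer).  Both triggers
report the day on which the fifth qualifying day completes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365
#: Calendar day of the warmest day of the sinusoidal annual cycle (mid July).
PEAK_DOY = 200

SPRING_TRIGGER_TEMP = 9.0
AUTUMN_TRIGGER_TEMP = 12.0
TRIGGER_RUN_DAYS = 5
#: Autumn trigger search starts 1 July so spring cold spells cannot fire it.
MIDSUMMER_DOY = 182
#: Forced relocation to overwintering sites if no autumn trigger fires (1 Nov).
AUTUMN_FALLBACK_DOY = 305


@dataclass(frozen=True)
class SiteClimate:
    """Parameters of the synthetic site climate.

    annual_mean_temp / seasonal_amplitude describe the sinusoid
    ``mean + amplitude * cos(2*pi*(doy - PEAK_DOY)/365)`` (degC); diurnal_range
    is tmax - tmin; day_to_day_sd is the stationary standard deviation of the
    AR(1) noise on the daily mean; autocorrelation its lag-1 coefficient;
    latitude (degrees N) sets day length.
    """

    annual_mean_temp: float = 9.8
    seasonal_amplitude: float = 6.5
    diurnal_range: float = 8.0
    day_to_day_sd: float = 3.2
    autocorrelation: float = 0.7
    latitude: float = 51.8

    def validate(self) -> None:
        if self.day_to_day_sd < 0:
            raise ValueError("day_to_day_sd must be non-negative")
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be non-negative")
        if not 0 <= self.autocorrelation < 1:
            raise ValueError("autocorrelation must be in [0, 1)")
        if self.diurnal_range < 0:
            raise ValueError("diurnal_range must be non-negative")


#: Site presets.  The UK sites are maritime; Berlin is more continental
#: (colder winters, warmer summers -> larger amplitude).
SITE_PRESETS: dict[str, SiteClimate] = {
    "rothamsted-like": SiteClimate(9.8, 6.5, 8.0, 3.2, 0.7, 51.8),
    "brooms-barn-like": SiteClimate(10.0, 6.8, 8.5, 3.2, 0.7, 52.3),
    "berlin-like": SiteClimate(9.5, 10.0, 9.0, 3.2, 0.7, 52.5),
}


def day_length_hours(doy, latitude: float):
    """Day length (h) from calendar day and latitude (standard formula)."""
    doy = np.asarray(doy, dtype=float)
    decl = -0.4093 * np.cos(2.0 * np.pi * (doy + 10.0) / DAYS_PER_YEAR)
    lat = np.deg2rad(latitude)
    cos_h0 = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_h0)


@dataclass
class WeatherSeries:
    """A multi-year daily weather record (plain numpy columns).

    ``year`` is 0-based simulation year, ``doy`` the 1..365 calendar day.
    Invariant: tmin <= tmean <= tmax and day_length in [0, 24].
    """

    year: np.ndarray
    doy: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    day_length: np.ndarray

    @property
    def tmean(self) -> np.ndarray:
        return 0.5 * (self.tmin + self.tmax)

    @property
    def n_days(self) -> int:
        return self.year.size

    def year_slice(self, year: int) -> slice:
        start = int(np.searchsorted(self.year, year))
        stop = int(np.searchsorted(self.year, year, side="right"))
        return slice(start, stop)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.year,
                "doy": self.doy,
                "tmin": self.tmin,
                "tmax": self.tmax,
                "day_length": self.day_length,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WeatherSeries":
        return cls(
            year=df["year"].to_numpy(int),
            doy=df["doy"].to_numpy(int),
            tmin=df["tmin"].to_numpy(float),
            tmax=df["tmax"].to_numpy(float),
            day_length=df["day_length"].to_numpy(float),
        )

    @classmethod
    def from_csv(cls, path) -> "WeatherSeries":
        return cls.from_frame(pd.read_csv(path))


def generate_daily_weather(
    site: SiteClimate, n_years: int, seed) -> WeatherSeries:
    """Generate ``n_years`` of synthetic daily weather.

    Daily mean = annual sinusoid + AR(1) noise with stationary sd
    ``site.day_to_day_sd``; tmin/tmax are mean -/+ half the diurnal range.
    Bit-reproducible for a fixed seed.
    """
    site.validate()
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_years * DAYS_PER_YEAR
    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), n_years)
    year = np.repeat(np.arange(n_years), DAYS_PER_YEAR)
    seasonal = site.annual_mean_temp + site.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - PEAK_DOY) / DAYS_PER_YEAR
    )
    if site.day_to_day_sd > 0:
        rho = site.autocorrelation
        z = rng.standard_normal(n)
        noise = np.empty(n)
        noise[0] = site.day_to_day_sd * z[0]
        innov_sd = site.day_to_day_sd * np.sqrt(1.0 - rho * rho)
        # AR(1) recursion; scipy.signal.lfilter would do, but the loop is tiny
        # relative to simulation cost and keeps the innovation scheme explicit.
        c = innov_sd * z
        for t in range(1, n):
            noise[t] = rho * noise[t - 1] + c[t]
    else:
        noise = np.zeros(n)
    tmean = seasonal + noise
    half = 0.5 * site.diurnal_range
    return WeatherSeries(
        year=year,
        doy=doy,
        tmin=tmean - half,
        tmax=tmean + half,
        day_length=day_length_hours(doy, site.latitude),
    )


def degree_days(tmean, base: float = 0.0):
    """Thermal time accumulated in one day: max(0, tmean - base)."""
    return np.maximum(0.0, np.asarray(tmean, dtype=float) - base)


def _find_run_day(doy: np.ndarray, qualifies: np.ndarray, run: int):
    count = 0
    for d, q in zip(doy, qualifies):
        count = count + 1 if q else 0
        if count >= run:
            return int(d)
    return None


def find_spring_emergence_day(
    series: WeatherSeries,
    year: int,
    threshold: float = SPRING_TRIGGER_TEMP,
    run: int = TRIGGER_RUN_DAYS,
):
    """Calendar day completing the first 5-day run of tmean > 9 degC.

    Searched in the first half of the year (before midsummer); ``None`` if the
    condition is never met.
    """
    sl = series.year_slice(year)
    doy = series.doy[sl]
    tmean = series.tmean[sl]
    mask = doy < MIDSUMMER_DOY
    return _find_run_day(doy[mask], tmean[mask] > threshold, run)


def find_autumn_return_day(
    series: WeatherSeries,
    year: int,
    threshold: float = AUTUMN_TRIGGER_TEMP,
    run: int = TRIGGER_RUN_DAYS,
):
    """Calendar day completing the first post-midsummer 5-day run of tmean < 12 degC."""
    sl = series.year_slice(year)
    doy = series.doy[sl]
    tmean = series.tmean[sl]
    mask = doy >= MIDSUMMER_DOY
    return _find_run_day(doy[mask], tmean[mask] < threshold, run)
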