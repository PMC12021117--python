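"""Environment generation and ingestion.

Provides (a) a synthetic hourly solar-irradiance-like generator — clear-sky
zenith geometry plus autocorrelated multiplicative weather attenuation — with
the statistical structure the tracking analysis assumes (zero-clipped daily
bell curves, seasonal amplitude/day-length modulation, hour-scale weather
autocorrelation), (b) a reader for PVGIS v5.2 ``seriescalc`` hourly payloads
(CSV or JSON), and (c) the construction of training/validation interval sets.

Normalization convention throughout: divide by the maximum over the full
series, so values lie in [0, 1] and at least one value equals 1.
"""

from __future__ import annotations

import io
import json
import re
import urllib.request
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import OptimalStateSeries

__all__ = [
    "SyntheticEnvConfig",
    "IntervalSet",
    "generate_clear_sky",
    "apply_weather",
    "synthetic_environment",
    "read_pvgis_hourly",
    "fetch_pvgis",
    "make_intervals",
    "normalize",
    "InvalidConfigError",
    "FormatError",
    "DegenerateDataError",
]

_EARTH_TILT_DEG = 23.44
_TROPICAL_YEAR_DAYS = 365.25


class InvalidConfigError(ValueError):
    """Configuration violates a precondition (latitude range, rho range, ...)."""


class FormatError(ValueError):
    """Input payload is not a well-formed uniform hourly series."""


class DegenerateDataError(ValueError):
    """Data cannot be normalized (e.g. all-zero irradiance)."""


@dataclass
class SyntheticEnvConfig:
    """Parameters of the synthetic environment.

    latitude
        Site latitude in degrees, in [-90, 90].
    start_day
        Day-of-year index (0-based) of the first simulated day.
    n_hours
        Number of hourly samples to generate.
    weather_rho
        Hourly lag-1 autocorrelation of the latent AR(1) weather process,
        in [0, 1).
    weather_sigma
        Innovation scale of the latent AR(1) process (>= 0); 0 disables
        weather entirely.
    seed
        Seed for the weather noise stream.
    start_year
        Calendar year anchoring the timestamps (UTC).
    """

    latitude: float = 45.0
    start_day: int = 0
    n_hours: int = 24 * 365
    weather_rho: float = 0.95
    weather_sigma: float = 0.5
    seed: int = 0
    start_year: int = 2005

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise InvalidConfigError("latitude must lie in [-90, 90]")
        if self.n_hours < 1:
            raise InvalidConfigError("n_hours must be >= 1")
        if not 0.0 <= self.weather_rho < 1.0:
            raise InvalidConfigError("weather_rho must lie in [0, 1)")
        if self.weather_sigma < 0.0:
            raise InvalidConfigError("weather_sigma must be >= 0")


@dataclass
class IntervalSet:
    """Positional windows ``(start, length)`` into a parent series."""

    starts: np.ndarray
    length: int
    mode: str  # "training" or "validation"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=int)

    def __len__(self) -> int:
        return len(self.starts)

    def windows(self, series):
        for start in self.starts:
            yield series.slice(int(start), self.length)


def _solar_elevation_factor(index: pd.DatetimeIndex, latitude: float) -> np.ndarray:
    """Zero-clipped sine of solar elevation on an hourly grid.

    Uses plain zenith-cosine geometry: declination
    delta(d) = -23.44 deg * cos(2*pi*(d+10)/365.25) and hour angle
    H = 15 deg * (hour_of_day - 12).  No atmospheric-mass correction; this is
    a statistical stand-in for irradiance, not a radiometric model.
    """
    day = index.dayofyear.to_numpy() - 1
    hour = index.hour.to_numpy() + index.minute.to_numpy() / 60.0
    phi = np.deg2rad(latitude)
    decl = np.deg2rad(-_EARTH_TILT_DEG) * np.cos(2 * np.pi * (day + 10) / _TROPICAL_YEAR_DAYS)
    hour_angle = np.deg2rad(15.0 * (hour - 12.0))
    elev = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(hour_angle)
    return np.maximum(0.0, elev)


def generate_clear_sky(config: SyntheticEnvConfig) -> OptimalStateSeries:
    """Deterministic clear-sky series, normalized to max 1."""
    start = pd.Timestamp(year=config.start_year, month=1, day=1) + pd.Timedelta(days=config.start_day)
    index = pd.date_range(start, periods=config.n_hours, freq="h")
    values = _solar_elevation_factor(index, config.latitude)
    return OptimalStateSeries(index, normalize(values))


def ar1_gaussian(n: int, rho: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) Gaussian process x_t = rho*x_{t-1} + sigma*eps_t."""
    if not 0.0 <= rho < 1.0:
        raise InvalidConfigError("rho must lie in [0, 1)")
    x = np.empty(n)
    innov = rng.standard_normal(n)
    x[0] = innov[0] * sigma / np.sqrt(1.0 - rho**2) if sigma > 0 else 0.0
    for t in range(1, n):
        x[t] = rho * x[t - 1] + sigma * innov[t]
    return x


def apply_weather(
    series: OptimalStateSeries,
    rho: float = 0.95,
    sigma: float = 0.5,
    seed: int = 0,
    bias: float = 2.0,
) -> OptimalStateSeries:
    """Multiply by an autocorrelated attenuation in (0, 1] and re-normalize.

    The attenuation is a logistic transform ``a_t = expit(bias + x_t)`` of a
    stationary AR(1) Gaussian ``x_t`` with hourly autocorrelation ``rho`` and
    innovation scale ``sigma``; ``bias`` sets the typical clearness (default
    2.0, i.e. a median attenuation of ~0.88).  ``sigma = 0`` returns the
    input unchanged.  Reproducible given ``seed``.
    """
    if sigma == 0.0:
        if not 0.0 <= rho < 1.0:
            raise InvalidConfigError("rho must lie in [0, 1)")
        return OptimalStateSeries(series.index, series.values.copy())
    rng = np.random.default_rng(seed)
    latent = ar1_gaussian(len(series), rho, sigma, rng)
    attenuation = 1.0 / (1.0 + np.exp(-(bias + latent)))
    return OptimalStateSeries(series.index, normalize(series.values * attenuation))


def synthetic_environment(config: SyntheticEnvConfig) -> OptimalStateSeries:
    """Clear-sky geometry with weather attenuation: the default test-bed."""
    clear = generate_clear_sky(config)
    return apply_weather(clear, config.weather_rho, config.weather_sigma, config.seed)


def normalize(values: np.ndarray) -> np.ndarray:
    """Divide by the maximum over the whole array (idempotent)."""
    values = np.asarray(values, dtype=float)
    peak = np.max(values) if len(values) else 0.0
    if peak <= 0.0:
        raise DegenerateDataError("cannot normalize a series with non-positive maximum")
    return values / peak


_PVGIS_TIME_RE = re.compile(r"^(\d{8}):(\d{2})(\d{2})$")


def _parse_pvgis_time(stamp: str) -> pd.Timestamp:
    match = _PVGIS_TIME_RE.match(stamp.strip())
    if match is None:
        raise FormatError(f"unrecognized PVGIS timestamp {stamp!r}")
    date, hh, _minutes = match.groups()
    # PVGIS stamps hourly records at an offset within the hour (e.g. HH:10);
    # truncate to the containing hour to obtain the uniform grid.
    return pd.Timestamp(f"{date[:4]}-{date[4:6]}-{date[6:8]} {hh}:00")


def read_pvgis_hourly(source) -> OptimalStateSeries:
    """Parse a PVGIS v5.2 ``seriescalc`` hourly payload (CSV or JSON).

    ``source`` may be a file path or the raw response text.  The global
    irradiance column (``G(i)`` or ``G(h)``) is normalized by the maximum over
    the entire parsed range.  A non-uniform hourly grid raises
    :class:`FormatError`; an all-zero series raises
    :class:`DegenerateDataError`.
    """
    text = _read_text(source)
    if not text.strip():
        raise FormatError("empty PVGIS payload")
    if text.lstrip().startswith("{"):
        stamps, values = _parse_pvgis_json(text)
    else:
        stamps, values = _parse_pvgis_csv(text)
    if not stamps:
        raise FormatError("no hourly records found in PVGIS payload")
    index = pd.DatetimeIndex(stamps)
    if len(index) > 1:
        deltas = np.diff(index.asi8)
        if not np.all(deltas == pd.Timedelta(hours=1).value):
            raise FormatError("PVGIS records do not form a uniform hourly grid")
    return OptimalStateSeries(index, normalize(np.asarray(values, dtype=float)))


def _read_text(source) -> str:
    if isinstance(source, io.IOBase):
        return source.read()
    text = str(source)
    if "\n" not in text and len(text) < 4096:
        try:
            with open(text, "r", encoding="utf-8") as handle:
                return handle.read()
        except OSError:
            pass
    return text


def _parse_pvgis_json(text: str):
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid PVGIS JSON: {exc}") from exc
    try:
        records = payload["outputs"]["hourly"]
    except (KeyError, TypeError) as exc:
        raise FormatError("PVGIS JSON lacks outputs.hourly records") from exc
    stamps, values = [], []
    for record in records:
        stamps.append(_parse_pvgis_time(record["time"]))
        irradiance = next((record[k] for k in ("G(i)", "G(h)") if k in record), None)
        if irradiance is None:
            raise FormatError("PVGIS record lacks a global-irradiance field")
        values.append(float(irradiance))
    return stamps, values


def _parse_pvgis_csv(text: str):
    stamps, values = [], []
    header_cols: list[str] | None = None
    irr_col = None
    for line in text.splitlines():
        line = line.strip()
        if header_cols is None:
            if line.lower().startswith("time,"):
                header_cols = [col.strip() for col in line.split(",")]
                for name in ("G(i)", "G(h)"):
                    if name in header_cols:
                        irr_col = header_cols.index(name)
                if irr_col is None:
                    raise FormatError("PVGIS CSV header lacks a global-irradiance column")
            continue
        if not line or _PVGIS_TIME_RE.match(line.split(",")[0]) is None:
            break  # footer metadata
        fields = line.split(",")
        stamps.append(_parse_pvgis_time(fields[0]))
        values.append(float(fields[irr_col]))
    if header_cols is None:
        raise FormatError("PVGIS CSV payload lacks a 'time,...' header line")
    return stamps, values


def fetch_pvgis(
    lat: float = 45.0,
    lon: float = 0.0,
    raddatabase: str = "PVGIS-ERA5",
    start_year: int | None = None,
    end_year: int | None = None,
    outputformat: str = "csv",
    timeout: float = 120.0,
) -> str:
    """Download a ``seriescalc`` payload from the PVGIS v5.2 web API.

    Thin optional helper; returns the raw response text for
    :func:`read_pvgis_hourly`.  Requires network access.
    """
    url = (
        "https://re.jrc.ec.europa.eu/api/v5_2/seriescalc"
        f"?lat={lat}&lon={lon}&raddatabase={raddatabase}&outputformat={outputformat}"
    )
    if start_year is not None:
        url += f"&startyear={start_year}"
    if end_year is not None:
        url += f"&endyear={end_year}"
    with urllib.request.urlopen(url, timeout=timeout) as response:
        return response.read().decode("utf-8")


def make_intervals(
    series,
    mode: str,
    interval_hours: int = 744,
    n_train: int = 365,
    spacing_hours: int = 720,
    seed: int | None = 0,
    n_validation: int | None = None,
) -> IntervalSet:
    """Construct training or validation windows into ``series``.

    training
        ``n_train`` windows of ``interval_hours`` samples with start indices
        drawn uniformly at random (overlap allowed), reproducible by ``seed``.
    validation
        Consecutive windows whose starts differ by ``spacing_hours`` (default
        720 h = 30 days); as many as fit unless ``n_validation`` is given.
    """
    n = len(series)
    if interval_hours > n:
        raise InvalidConfigError(
            f"a {interval_hours}-h window does not fit a {n}-h series"
        )
    if mode == "training":
        rng = np.random.default_rng(seed)
        starts = rng.integers(0, n - interval_hours + 1, size=n_train)
        return IntervalSet(starts, interval_hours, "training", seed=seed)
    if mode == "validation":
        max_fit = (n - interval_hours) // spacing_hours + 1
        count = max_fit if n_validation is None else n_validation
        if count > max_fit:
            raise InvalidConfigError(
                f"{count} validation windows of {interval_hours} h spaced {spacing_hours} h "
                f"do not fit a {n}-h series"
            )
        starts = np.arange(count) * spacing_hours
        return IntervalSet(starts, interval_hours, "validation", seed=None)
    raise InvalidConfigError(f"unknown interval mode {mode!r}")
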