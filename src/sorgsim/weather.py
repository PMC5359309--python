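"""Daily weather containers, derived quantities, and synthetic climatology.

This module owns everything the simulator needs from the atmosphere: reading
and writing APSIM-style ``.met`` files and their CSV equivalent, the annual
temperature statistics (``tav``/``amp``) used by soil-temperature conventions,
astronomical day length, diurnal interpolation of temperature to an hourly
grid, hourly and daily vapor pressure deficit, and a stochastic weather
generator that emulates a central-Texas (College Station-like) climatology:
sinusoidal seasonal cycles for temperature and solar radiation, and a
two-state Markov occurrence chain with gamma-distributed amounts for rainfall
whose wet-day probability dips in mid-summer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as _date

import numpy as np
import pandas as pd

__all__ = [
    "DailyWeather",
    "WeatherSeries",
    "SynthWeatherParams",
    "WeatherError",
    "svp",
    "hourly_vpd",
    "daily_vpd",
    "day_length",
    "compute_tav_amp",
    "interpolate_hourly_temperature",
    "hourly_temperature_curve",
    "read_met",
    "read_weather_csv",
    "write_met",
    "write_weather_csv",
    "generate_synthetic_weather",
]

#: Hour-center grid used everywhere sub-daily quantities are evaluated.
HOUR_CENTERS = np.arange(24, dtype=float) + 0.5

#: Sun elevation angle (degrees) defining the photoperiod-relevant day length.
DEFAULT_TWILIGHT_DEG = -2.2


class WeatherError(ValueError):
    """Raised for malformed or incomplete weather inputs."""


@dataclass(frozen=True)
class DailyWeather:
    """One day of weather.

    Attributes
    ----------
    date : datetime.date
    tmax, tmin : float
        Daily maximum/minimum air temperature, degC.
    radn : float
        Incident shortwave radiation, MJ m-2 d-1.
    rain : float
        Rainfall, mm d-1.
    """

    date: _date
    tmax: float
    tmin: float
    radn: float
    rain: float

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise WeatherError(
                f"{self.date}: tmax ({self.tmax}) < tmin ({self.tmin})"
            )
        if self.radn < 0:
            raise WeatherError(f"{self.date}: negative radiation {self.radn}")
        if self.rain < 0:
            raise WeatherError(f"{self.date}: negative rainfall {self.rain}")


REQUIRED_COLUMNS = ("date", "tmax", "tmin", "radn", "rain")


@dataclass
class WeatherSeries:
    """An ordered, gap-free daily weather record for one site.

    ``data`` holds columns ``date`` (datetime64), ``tmax``, ``tmin``,
    ``radn`` and ``rain``.  ``tav`` (annual mean of monthly mean temperature)
    and ``amp`` (annual amplitude of monthly means) are derived on
    construction when the series spans at least a full year and are otherwise
    left as ``nan`` unless supplied explicitly.
    """

    data: pd.DataFrame
    latitude: float
    tav: float = float("nan")
    amp: float = float("nan")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise WeatherError(f"missing weather columns: {missing}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].reset_index(drop=True)
        df["date"] = pd.to_datetime(df["date"])
        bad = df.index[df["tmax"] < df["tmin"]]
        if len(bad):
            rows = ", ".join(
                f"row {i} ({df.loc[i, 'date'].date()})" for i in bad[:5]
            )
            raise WeatherError(f"tmax < tmin at {rows}")
        if (df["radn"] < 0).any() or (df["rain"] < 0).any():
            raise WeatherError("negative radiation or rainfall present")
        deltas = df["date"].diff().dt.days.iloc[1:]
        if (deltas <= 0).any():
            i = int(deltas[deltas <= 0].index[0])
            raise WeatherError(
                f"dates not strictly increasing at row {i} "
                f"({df.loc[i, 'date'].date()})"
            )
        if (deltas > 1).any():
            i = int(deltas[deltas > 1].index[0])
            gap = (df.loc[i - 1, "date"] + pd.Timedelta(days=1)).date()
            raise WeatherError(f"missing day in weather series: {gap}")
        self.data = df
        if math.isnan(self.tav) or math.isnan(self.amp):
            try:
                self.tav, self.amp = compute_tav_amp(self)
            except WeatherError:
                pass  # short series: leave nan

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dates(self) -> pd.Series:
        return self.data["date"]

    def records(self):
        """Iterate rows as :class:`DailyWeather` objects."""
        for row in self.data.itertuples(index=False):
            yield DailyWeather(
                row.date.date(), row.tmax, row.tmin, row.radn, row.rain
            )

    def row(self, i: int) -> DailyWeather:
        r = self.data.iloc[i]
        return DailyWeather(
            r["date"].date(), r["tmax"], r["tmin"], r["radn"], r["rain"]
        )

    def index_of(self, day: _date) -> int:
        first = self.data["date"].iloc[0].date()
        i = (day - first).days
        if i < 0 or i >= len(self.data):
            raise WeatherError(f"date {day} outside weather series")
        return i

    def slice_days(self, start: _date, n_days: int) -> "WeatherSeries":
        i = self.index_of(start)
        if i + n_days > len(self.data):
            last = self.data["date"].iloc[-1].date()
            raise WeatherError(
                f"weather series ends {last}; need {n_days} days from {start}"
            )
        sub = self.data.iloc[i : i + n_days].reset_index(drop=True)
        return WeatherSeries(sub, self.latitude, self.tav, self.amp)

    def years(self) -> list[int]:
        return sorted(self.data["date"].dt.year.unique().tolist())


# ---------------------------------------------------------------------------
# Vapor pressure
# ---------------------------------------------------------------------------

def svp(temp_c):
    """Saturation vapor pressure (kPa) by the Tetens formula."""
    temp_c = np.asarray(temp_c, dtype=float)
    out = 0.6106 * np.exp(17.27 * temp_c / (temp_c + 237.3))
    return float(out) if out.ndim == 0 else out


def hourly_vpd(hourly_temp, tmin):
    """VPD (kPa) at an hourly temperature, assuming dewpoint = daily tmin.

    The ambient vapor pressure is taken as svp(tmin); the deficit is clamped
    at zero so pre-dawn hours (temp ~ tmin) carry no atmospheric demand.
    """
    out = np.maximum(svp(hourly_temp) - svp(tmin), 0.0)
    return float(out) if np.ndim(out) == 0 else out


def daily_vpd(tmax: float, tmin: float, svp_fraction: float = 0.75) -> float:
    """Daily effective VPD (kPa) as a fraction of the svp(tmax)-svp(tmin) span."""
    if tmax < tmin:
        raise WeatherError(f"tmax ({tmax}) < tmin ({tmin})")
    return svp_fraction * (svp(tmax) - svp(tmin))


# ---------------------------------------------------------------------------
# tav / amp
# ---------------------------------------------------------------------------

def compute_tav_amp(series: "WeatherSeries") -> tuple[float, float]:
    """Annual average temperature and annual amplitude of monthly means.

    Monthly means of (tmax+tmin)/2 are pooled by calendar month across the
    series; ``tav`` is the mean of the 12 month-of-year means and ``amp``
    their range.  Requires every calendar month to be represented.
    """
    df = series.data
    tmean = (df["tmax"] + df["tmin"]) / 2.0
    monthly = tmean.groupby(
        [df["date"].dt.year, df["date"].dt.month]
    ).mean()
    by_month = monthly.groupby(level=1).mean()
    if len(by_month) < 12:
        raise WeatherError(
            f"tav/amp needs all 12 calendar months; found {len(by_month)}"
        )
    return float(by_month.mean()), float(by_month.max() - by_month.min())


# ---------------------------------------------------------------------------
# Day length
# ---------------------------------------------------------------------------

def solar_declination(day_of_year) -> float:
    """Solar declination (radians)."""
    doy = np.asarray(day_of_year, dtype=float)
    out = np.radians(23.45) * np.sin(2.0 * np.pi * (284.0 + doy) / 365.25)
    return float(out) if out.ndim == 0 else out


def day_length(latitude: float, day_of_year, twilight_deg: float = 0.0):
    """Astronomical day length (hours) for a twilight sun-elevation angle.

    ``twilight_deg`` < 0 counts hours where the sun is slightly below the
    horizon (e.g. -2.2 deg, the convention used for sorghum photoperiod).
    Polar latitudes are unsupported.
    """
    if abs(latitude) >= 66.5:
        raise WeatherError(f"latitude {latitude} unsupported (polar)")
    decl = solar_declination(day_of_year)
    lat = math.radians(latitude)
    a = math.radians(twilight_deg)
    cos_h = (math.sin(a) - math.sin(lat) * np.sin(decl)) / (
        math.cos(lat) * np.cos(decl)
    )
    cos_h = np.clip(cos_h, -1.0, 1.0)
    out = 2.0 * np.degrees(np.arccos(cos_h)) / 15.0
    return float(out) if np.ndim(out) == 0 else out


def sunrise_sunset(
    latitude: float, day_of_year: int, twilight_deg: float = 0.0
) -> tuple[float, float]:
    """(sunrise, sunset) in local solar hours, symmetric around noon."""
    dl = day_length(latitude, day_of_year, twilight_deg)
    return 12.0 - dl / 2.0, 12.0 + dl / 2.0


# ---------------------------------------------------------------------------
# Diurnal temperature interpolation
# ---------------------------------------------------------------------------

def hourly_temperature_curve(
    prev: DailyWeather,
    today: DailyWeather,
    nxt: DailyWeather,
    sunrise: float,
    sunset: float,
    peak_offset: float = 2.0,
    dusk_fraction: float = 0.4,
    night_decay: float = 2.5,
):
    """Continuous piecewise diurnal temperature function T(t), t in [0, 24).

    Two daytime sinusoids (rise from the pre-dawn minimum to tmax at
    ``sunset - peak_offset``, then decay to a dusk temperature) are joined to
    an exponential nighttime decay toward the following day's tmin.  All
    junctions are continuous; the daily maximum equals tmax exactly once, at
    the peak hour.
    """
    if not sunrise < sunset:
        raise WeatherError("sunrise must precede sunset")
    t_peak = max(sunset - peak_offset, sunrise + 0.25)
    tmax, tmin = today.tmax, today.tmin
    # Dusk anchors for yesterday's and today's nighttime branches.
    dusk_prev = prev.tmax - dusk_fraction * (prev.tmax - tmin)
    dusk_today = tmax - dusk_fraction * (tmax - nxt.tmin)
    night_len = (sunrise + 24.0) - sunset

    def at_dawn() -> float:
        # yesterday's night branch evaluated at today's sunrise
        frac = (sunrise + 24.0 - sunset) / night_len
        return tmin + (dusk_prev - tmin) * math.exp(-night_decay * frac)

    t_dawn = at_dawn()

    def curve(t: float) -> float:
        t = t % 24.0
        if t < sunrise:
            frac = (t + 24.0 - sunset) / night_len
            return tmin + (dusk_prev - tmin) * math.exp(-night_decay * frac)
        if t <= t_peak:
            phase = (t - sunrise) / (t_peak - sunrise)
            return t_dawn + (tmax - t_dawn) * math.sin(0.5 * math.pi * phase)
        if t <= sunset:
            phase = (t - t_peak) / (sunset - t_peak)
            return dusk_today + (tmax - dusk_today) * math.cos(
                0.5 * math.pi * phase
            )
        frac = (t - sunset) / night_len
        return nxt.tmin + (dusk_today - nxt.tmin) * math.exp(
            -night_decay * frac
        )

    return curve, t_peak


def interpolate_hourly_temperature(
    prev: DailyWeather,
    today: DailyWeather,
    nxt: DailyWeather,
    sunrise: float,
    sunset: float,
    **kwargs,
) -> np.ndarray:
    """24 hourly temperatures at hour centers, peak snapped onto the grid.

    The peak hour is moved to the nearest hour center so the sampled series
    attains today's tmax exactly.
    """
    curve, t_peak = hourly_temperature_curve(
        prev, today, nxt, sunrise, sunset, **kwargs
    )
    snapped = float(np.round(t_peak - 0.5) + 0.5)
    if sunrise < snapped < sunset:
        kwargs = dict(kwargs)
        kwargs["peak_offset"] = sunset - snapped
        curve, t_peak = hourly_temperature_curve(
            prev, today, nxt, sunrise, sunset, **kwargs
        )
    return np.array([curve(t) for t in HOUR_CENTERS])


# ---------------------------------------------------------------------------
# .met / CSV I/O
# ---------------------------------------------------------------------------

def read_met(path) -> WeatherSeries:
    """Read an APSIM-dialect .met file.

    Header lines of the form ``latitude = 30.589`` (and optionally ``tav``,
    ``amp``) precede a whitespace-delimited column block
    ``year day radn maxt mint rain`` followed by a units line.
    """
    header: dict[str, float] = {}
    col_names: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("!") or line.startswith("["):
            continue
        if "=" in line:
            key, _, val = line.partition("=")
            key = key.strip().lower()
            val = val.split("!")[0].split("(")[0].strip()
            try:
                header[key] = float(val)
            except ValueError:
                pass
            continue
        parts = line.split()
        if col_names is None:
            if parts[0].lower() in ("year", "date"):
                col_names = [p.lower() for p in parts]
            continue
        if parts[0].startswith("("):  # units line
            continue
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise WeatherError(f"{path}: bad value on line {lineno}: {exc}")
    if col_names is None or not rows:
        raise WeatherError(f"{path}: no column block found")
    needed = {"year", "day", "radn", "maxt", "mint", "rain"}
    if not needed.issubset(col_names):
        raise WeatherError(
            f"{path}: missing columns {sorted(needed - set(col_names))}"
        )
    if "latitude" not in header:
        raise WeatherError(f"{path}: header does not declare latitude")
    arr = pd.DataFrame(rows, columns=col_names)
    dates = pd.to_datetime(
        arr["year"].astype(int).astype(str), format="%Y"
    ) + pd.to_timedelta(arr["day"].astype(int) - 1, unit="D")
    df = pd.DataFrame(
        {
            "date": dates,
            "tmax": arr["maxt"],
            "tmin": arr["mint"],
            "radn": arr["radn"],
            "rain": arr["rain"],
        }
    )
    return WeatherSeries(
        df,
        latitude=header["latitude"],
        tav=header.get("tav", float("nan")),
        amp=header.get("amp", float("nan")),
    )


def read_weather_csv(path, latitude: float | None = None) -> WeatherSeries:
    """Read the CSV dialect: columns date,tmax,tmin,radn,rain (ISO dates).

    An optional comment header ``# latitude = <deg>`` may declare the site
    latitude; otherwise pass it explicitly.
    """
    with open(path) as fh:
        first = fh.readline()
    header_lat = None
    skip = 0
    if first.lstrip().startswith("#"):
        skip = 1
        if "latitude" in first:
            header_lat = float(first.split("=")[1])
    df = pd.read_csv(path, skiprows=skip)
    lat = latitude if latitude is not None else header_lat
    if lat is None:
        raise WeatherError(f"{path}: latitude not declared and not supplied")
    return WeatherSeries(df, latitude=float(lat))


def write_met(series: WeatherSeries, path) -> None:
    df = series.data
    with open(path, "w") as fh:
        fh.write("[weather.met.weather]\n")
        fh.write(f"latitude = {series.latitude:.5f}   (DECIMAL DEGREES)\n")
        if not math.isnan(series.tav):
            fh.write(f"tav = {series.tav:.2f}   (oC)\n")
        if not math.isnan(series.amp):
            fh.write(f"amp = {series.amp:.2f}   (oC)\n")
        fh.write("year day radn maxt mint rain\n")
        fh.write("() () (MJ/m^2) (oC) (oC) (mm)\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.date.year} {row.date.dayofyear} "
                f"{row.radn:.2f} {row.tmax:.2f} {row.tmin:.2f} "
                f"{row.rain:.2f}\n"
            )


def write_weather_csv(series: WeatherSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# latitude = {series.latitude:.5f}\n")
        out = series.data.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(fh, index=False, float_format="%.2f")


# ---------------------------------------------------------------------------
# Synthetic weather generator
# ---------------------------------------------------------------------------

@dataclass
class SynthWeatherParams:
    """Parameters of the synthetic central-Texas climatology.

    Defaults emulate College Station, TX: mean annual temperature ~20.5 degC
    peaking in late July, ~11.5 degC diurnal range, solar radiation between
    ~10 (winter) and ~23 (summer) MJ m-2 d-1, and intermittent rainfall from
    a first-order two-state occurrence chain with gamma amounts whose wet-day
    probability dips in mid-summer, yielding a mean cropping-season
    (Apr 15 + 200 d) total near 560 mm.
    """

    latitude: float = 30.589
    temp_mean: float = 20.5          # degC, annual mean
    temp_seasonal_amp: float = 9.5   # degC, half peak-to-trough
    temp_phase_doy: float = 205.0    # warmest day of year
    diurnal_range: float = 11.5      # degC tmax - tmin
    temp_noise_sd: float = 2.0       # degC, AR(1)-free daily noise on the mean
    range_noise_sd: float = 1.5      # degC
    radn_mean: float = 16.5          # MJ m-2 d-1, annual mean
    radn_amp: float = 6.2            # MJ m-2 d-1
    radn_phase_doy: float = 180.0    # brightest day of year
    radn_noise_sd: float = 2.5
    wet_radn_factor: float = 0.8     # cloudiness on rain days
    p_wet_wet: float = 0.45          # P(wet | previous wet)
    p_dry_wet: float = 0.20          # P(wet | previous dry), before seasonality
    summer_dry_depth: float = 0.55   # fractional dip in wet probability
    summer_dry_center_doy: float = 225.0
    summer_dry_width: float = 40.0   # gaussian width, days
    rain_shape: float = 0.65         # gamma shape of wet-day amounts
    rain_scale: float = 19.0         # gamma scale, mm
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_wet_wet, self.p_dry_wet):
            if not 0.0 <= p <= 1.0:
                raise WeatherError(f"rain probability {p} outside [0, 1]")
        if self.rain_shape <= 0 or self.rain_scale <= 0:
            raise WeatherError("gamma shape/scale must be positive")

    def season_rain_target(self) -> float:
        """Mean cropping-season rainfall (mm) implied by the chain, by
        numerically propagating the time-varying wet probability."""
        doy = np.arange(105, 305)  # Apr 15 + 200 days
        p01 = self.p_dry_wet * self._seasonal_factor(doy)
        p11 = self.p_wet_wet
        pi = np.empty(doy.size)
        pi[0] = p01[0] / max(p01[0] + 1.0 - p11, 1e-9)
        for i in range(1, doy.size):
            pi[i] = pi[i - 1] * p11 + (1.0 - pi[i - 1]) * p01[i]
        return float(pi.sum() * self.rain_shape * self.rain_scale)

    def _seasonal_factor(self, doy):
        return 1.0 - self.summer_dry_depth * np.exp(
            -(((np.asarray(doy, float) - self.summer_dry_center_doy)
               / self.summer_dry_width) ** 2)
        )


def generate_synthetic_weather(
    params: SynthWeatherParams | None = None,
    years: int = 1,
    start_year: int = 2001,
    seed: int | None = None,
) -> WeatherSeries:
    """Generate ``years`` whole calendar years of synthetic daily weather.

    Reproducible: the same parameters and seed always give the same series.
    ``seed`` overrides ``params.seed`` when given.
    """
    p = params or SynthWeatherParams()
    rng = np.random.default_rng(p.seed if seed is None else seed)
    dates = pd.date_range(
        f"{start_year}-01-01", f"{start_year + years - 1}-12-31", freq="D"
    )
    doy = dates.dayofyear.to_numpy(dtype=float)
    n = len(dates)

    tmean = p.temp_mean + p.temp_seasonal_amp * np.cos(
        2.0 * np.pi * (doy - p.temp_phase_doy) / 365.25
    ) + rng.normal(0.0, p.temp_noise_sd, n)
    trange = np.maximum(
        p.diurnal_range + rng.normal(0.0, p.range_noise_sd, n), 0.0
    )

    # rainfall occurrence chain with a mid-summer dry dip
    p01 = p.p_dry_wet * p._seasonal_factor(doy)
    u = rng.random(n)
    wet = np.zeros(n, dtype=bool)
    prev_wet = False
    for i in range(n):
        thresh = p.p_wet_wet if prev_wet else p01[i]
        prev_wet = wet[i] = u[i] < thresh
    rain = np.zeros(n)
    n_wet = int(wet.sum())
    if n_wet:
        rain[wet] = rng.gamma(p.rain_shape, p.rain_scale, n_wet)

    radn = p.radn_mean + p.radn_amp * np.cos(
        2.0 * np.pi * (doy - p.radn_phase_doy) / 365.25
    ) + rng.normal(0.0, p.radn_noise_sd, n)
    radn = np.where(wet, radn * p.wet_radn_factor, radn)
    radn = np.clip(radn, 0.5, 35.0)

    df = pd.DataFrame(
        {
            "date": dates,
            "tmax": tmean + trange / 2.0,
            "tmin": tmean - trange / 2.0,
            "radn": radn,
            "rain": rain,
        }
    )
    return WeatherSeries(df, latitude=p.latitude)
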