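"""Shared fixtures: synthetic weather and cached season runs."""

import numpy as np
import pytest

from sorgsim import engine as eng
from sorgsim import soilwater as sw
from sorgsim import weather as wx


@pytest.fixture(scope="session")
def synth_series() -> wx.WeatherSeries:
    """Three years of the default College-Station-like climatology."""
    return wx.generate_synthetic_weather(
        wx.SynthWeatherParams(), years=3, seed=1
    )


@pytest.fixture(scope="session")
def dry_series(synth_series) -> wx.WeatherSeries:
    """Same climatology but with rain shut off after day-of-year 180
    (terminal drought for an April 15 sowing: no rain past ~75 DAS)."""
    df = synth_series.data.copy()
    df.loc[df["date"].dt.dayofyear > 180, "rain"] = 0.0
    return wx.WeatherSeries(df, synth_series.latitude)


@pytest.fixture(scope="session")
def rainfed_run(synth_series):
    return eng.run_season(synth_series, 2002, eng.SimulationConfig())


@pytest.fixture(scope="session")
def irrigated_run(synth_series):
    cfg = eng.SimulationConfig(
        irrigation=sw.IrrigationRegime("unlimited")
    )
    return eng.run_season(synth_series, 2002, cfg)


@pytest.fixture()
def met_text(tmp_path):
    """A handcrafted 3-day .met fixture file."""
    text = (
        "[weather.met.weather]\n"
        "latitude = 30.589   (DECIMAL DEGREES)\n"
        "tav = 20.0 (oC)\n"
        "amp = 17.0 (oC)\n"
        "year day radn maxt mint rain\n"
        "() () (MJ/m^2) (oC) (oC) (mm)\n"
        "2008 100 18.0 28.0 15.0 0.0\n"
        "2008 101 20.5 29.5 16.0 5.2\n"
        "2008 102 16.0 27.0 17.5 12.0\n"
    )
    path = tmp_path / "fixture.met"
    path.write_text(text)
    return path
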