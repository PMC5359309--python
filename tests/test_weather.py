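"""Weather module: I/O, derived statistics, diurnal interpolation, generator."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sorgsim import weather as wx


def tetens(t):
    return 0.6106 * math.exp(17.27 * t / (t + 237.3))


class TestMetIO:
    def test_met_round_trip_preserves_fixture(self, met_text, tmp_path):
        series = wx.read_met(met_text)
        assert len(series) == 3
        assert series.latitude == pytest.approx(30.589)
        assert series.tav == pytest.approx(20.0)
        first = series.row(0)
        assert (first.tmax, first.tmin, first.radn, first.rain) == (
            28.0, 15.0, 18.0, 0.0
        )
        out = tmp_path / "rt.met"
        wx.write_met(series, out)
        again = wx.read_met(out)
        pd.testing.assert_frame_equal(series.data, again.data)

    def test_missing_day_error_names_the_gap(self, met_text):
        text = met_text.read_text().replace("2008 101 20.5 29.5 16.0 5.2\n", "")
        met_text.write_text(text)
        with pytest.raises(wx.WeatherError, match="2008-04-10"):
            wx.read_met(met_text)

    def test_tmax_below_tmin_reported_with_row(self, met_text):
        text = met_text.read_text().replace(
            "2008 101 20.5 29.5 16.0 5.2", "2008 101 20.5 10.0 16.0 5.2"
        )
        met_text.write_text(text)
        with pytest.raises(wx.WeatherError, match="row 1"):
            wx.read_met(met_text)

    def test_csv_variant_equals_met_path(self, met_text, tmp_path):
        series = wx.read_met(met_text)
        csv = tmp_path / "same.csv"
        wx.write_weather_csv(series, csv)
        other = wx.read_weather_csv(csv)
        assert other.latitude == pytest.approx(series.latitude)
        pd.testing.assert_frame_equal(series.data, other.data)


class TestTavAmp:
    def test_constant_year_gives_mean_and_zero_amplitude(self):
        dates = pd.date_range("2001-01-01", "2001-12-31")
        df = pd.DataFrame(
            {"date": dates, "tmax": 20.0, "tmin": 20.0, "radn": 15.0,
             "rain": 0.0}
        )
        series = wx.WeatherSeries(df, latitude=30.0)
        tav, amp = wx.compute_tav_amp(series)
        assert tav == pytest.approx(20.0)
        assert amp == pytest.approx(0.0)

    def test_sinusoid_recovers_mean_and_range(self):
        # oracle: brute-force monthly means of the generated series
        dates = pd.date_range("2001-01-01", "2001-12-31")
        doy = dates.dayofyear.to_numpy()
        tmean = 20.0 + 10.0 * np.sin(2 * np.pi * doy / 365)
        df = pd.DataFrame(
            {"date": dates, "tmax": tmean, "tmin": tmean, "radn": 15.0,
             "rain": 0.0}
        )
        monthly = (
            pd.Series(tmean, index=dates).groupby(dates.month).mean()
        )
        tav, amp = wx.compute_tav_amp(wx.WeatherSeries(df, 30.0))
        assert tav == pytest.approx(monthly.mean())
        assert amp == pytest.approx(monthly.max() - monthly.min())
        assert tav == pytest.approx(20.0, abs=0.3)
        assert amp == pytest.approx(20.0, abs=1.0)

    def test_two_identical_years_match_one(self):
        dates1 = pd.date_range("2001-01-01", "2001-12-31")
        doy = dates1.dayofyear.to_numpy()
        tmean = 18.0 + 8.0 * np.sin(2 * np.pi * doy / 365)

        def build(years):
            frames = []
            for y in years:
                d = pd.date_range(f"{y}-01-01", f"{y}-12-31")
                t = 18.0 + 8.0 * np.sin(2 * np.pi * d.dayofyear / 365)
                frames.append(
                    pd.DataFrame({"date": d, "tmax": t, "tmin": t,
                                  "radn": 15.0, "rain": 0.0})
                )
            return wx.WeatherSeries(pd.concat(frames, ignore_index=True), 30.0)

        one = wx.compute_tav_amp(build([2001]))
        two = wx.compute_tav_amp(build([2001, 2002]))
        assert one[0] == pytest.approx(two[0], abs=0.05)
        assert one[1] == pytest.approx(two[1], abs=0.05)

    def test_short_series_rejected(self):
        dates = pd.date_range("2001-01-01", "2001-06-30")
        df = pd.DataFrame({"date": dates, "tmax": 20.0, "tmin": 10.0,
                           "radn": 15.0, "rain": 0.0})
        series = wx.WeatherSeries(df, 30.0)
        with pytest.raises(wx.WeatherError, match="12 calendar months"):
            wx.compute_tav_amp(series)


class TestDayLength:
    def test_equator_always_twelve_hours(self):
        for doy in (1, 80, 172, 265, 355):
            assert wx.day_length(0.0, doy, 0.0) == pytest.approx(12.0, abs=1e-9)

    def test_college_station_summer_solstice(self):
        # standard solar-declination oracle, evaluated independently
        lat, doy = 30.589, 172
        decl = math.radians(23.45) * math.sin(
            2 * math.pi * (284 + doy) / 365.25
        )
        cos_h = -math.tan(math.radians(lat)) * math.tan(decl)
        expect = 2 * math.degrees(math.acos(cos_h)) / 15
        assert wx.day_length(lat, doy, 0.0) == pytest.approx(expect, abs=1e-9)
        assert expect == pytest.approx(14.0, abs=0.15)

    def test_crossing_below_12_4_h_falls_in_september(self):
        dl = np.array(
            [wx.day_length(30.589, d, -2.2) for d in range(172, 330)]
        )
        cross_doy = 172 + int(np.argmax(dl < 12.4))
        # doy 244-273 is September
        assert 244 <= cross_doy <= 273

    def test_polar_latitude_rejected(self):
        with pytest.raises(wx.WeatherError, match="polar"):
            wx.day_length(70.0, 172)


def _day(t_max, t_min):
    import datetime

    return wx.DailyWeather(datetime.date(2001, 7, 1), t_max, t_min, 20.0, 0.0)


class TestHourlyTemperature:
    def test_degenerate_range_is_flat(self):
        d = _day(15.0, 15.0)
        temps = wx.interpolate_hourly_temperature(d, d, d, 6.0, 19.0)
        assert np.allclose(temps, 15.0)

    def test_minimum_at_sunrise_and_max_equals_tmax(self):
        d = _day(34.0, 22.0)
        sunrise, sunset = 6.5, 19.5
        temps = wx.interpolate_hourly_temperature(d, d, d, sunrise, sunset)
        assert temps.max() == pytest.approx(34.0, abs=1e-9)
        assert (temps <= 34.0 + 1e-9).all()
        argmin_hour = wx.HOUR_CENTERS[int(np.argmin(temps))]
        assert abs(argmin_hour - sunrise) <= 1.0

    def test_segment_junctions_continuous(self):
        d = _day(31.0, 18.0)
        curve, t_peak = wx.hourly_temperature_curve(d, d, d, 6.0, 19.0)
        for junction in (6.0, t_peak, 19.0):
            lo = curve(junction - 1e-9)
            hi = curve(junction + 1e-9)
            assert abs(hi - lo) < 1e-6


class TestVpd:
    def test_zero_at_dewpoint(self):
        assert wx.hourly_vpd(20.0, 20.0) == 0.0

    def test_tetens_value(self):
        # direct evaluation of the Tetens formula
        expect = tetens(30.0) - tetens(20.0)
        assert wx.hourly_vpd(30.0, 20.0) == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(1.904, abs=2e-3)

    def test_monotone_in_temperature(self):
        temps = np.linspace(20.1, 45.0, 50)
        vals = wx.hourly_vpd(temps, 20.0)
        assert (np.diff(vals) > 0).all()

    def test_daily_vpd_fraction(self):
        expect = 0.75 * (tetens(30.0) - tetens(20.0))
        assert wx.daily_vpd(30.0, 20.0, 0.75) == pytest.approx(expect)
        assert wx.daily_vpd(25.0, 25.0) == 0.0

    def test_daily_vpd_bounded_by_hourly_extremes(self, synth_series):
        for row in synth_series.data.iloc[180:200].itertuples():
            daily = wx.daily_vpd(row.tmax, row.tmin)
            assert wx.hourly_vpd(row.tmin, row.tmin) <= daily
            assert daily <= wx.hourly_vpd(row.tmax, row.tmin) + 1e-12


class TestSyntheticGenerator:
    def test_absorbing_dry_state_gives_zero_rain(self):
        p = wx.SynthWeatherParams(p_wet_wet=0.0, p_dry_wet=0.0)
        series = wx.generate_synthetic_weather(p, years=2, seed=5)
        assert (series.data["rain"] == 0.0).all()

    def test_same_seed_identical_series(self):
        a = wx.generate_synthetic_weather(years=2, seed=11)
        b = wx.generate_synthetic_weather(years=2, seed=11)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_seasonal_rainfall_matches_configured_moments(self):
        # Monte-Carlo check of mean cropping-season rainfall vs the
        # chain-implied target over 200 simulated years
        p = wx.SynthWeatherParams()
        series = wx.generate_synthetic_weather(p, years=200, seed=42)
        rain = series.data["rain"].to_numpy()
        dates = series.data["date"]
        totals = []
        for y in range(2001, 2200):
            i = series.index_of(pd.Timestamp(f"{y}-04-15").date())
            if i + 200 <= len(rain):
                totals.append(rain[i : i + 200].sum())
        mean = np.mean(totals)
        assert mean == pytest.approx(p.season_rain_target(), rel=0.05)

    def test_weather_invariants(self, synth_series):
        df = synth_series.data
        assert (df["tmax"] >= df["tmin"]).all()
        assert (df["radn"] > 0).all()
        assert (df["rain"] >= 0).all()


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    tmin=st.floats(-5.0, 28.0),
    span=st.floats(0.0, 20.0),
    hour_frac=st.floats(0.0, 1.0),
)
def test_hourly_temperature_bounded_by_daily_extremes(tmin, span, hour_frac):
    """The diurnal curve never exceeds tmax nor undershoots tmin."""
    tmax = tmin + span
    d = _day(tmax, tmin)
    curve, _ = wx.hourly_temperature_curve(d, d, d, 6.0, 19.0)
    t = 24.0 * hour_frac
    val = curve(t)
    assert tmin - 1e-9 <= val <= tmax + 1e-9
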