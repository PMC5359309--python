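"""Daily simulation loop: weather -> phenology -> canopy -> water -> biomass.

``run_season`` advances one cropping season from sowing to a fixed season
end (200 days after sowing by default), producing one output record per day.
Each day follows a fixed order: derive weather, advance phenology, grow the
potential canopy, compute the radiation-limited biomass rate, resolve water
(either the hourly VPD-limited transpiration sub-model or the daily
demand/supply rule), extract soil water, accumulate and partition biomass,
senesce, evaporate, then apply irrigation and infiltrate.  The season water
budget closes exactly: rain + irrigation = transpiration + evaporation +
runoff + storage change.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date as _date, timedelta

import numpy as np
import pandas as pd

from . import biomass as bm
from . import canopy as cp
from . import phenology as ph
from . import soilwater as sw
from . import vpd_transpiration as vt
from . import weather as wx

__all__ = [
    "GenotypeBundle",
    "SimulationConfig",
    "run_season",
    "run_multi_year",
    "season_summary",
]


@dataclass(frozen=True)
class GenotypeBundle:
    """Everything genotype-specific: phenology, canopy, growth, trait."""

    phenology: ph.GenotypePhenology = ph.TEXAS_ENERGY
    canopy: cp.CanopyParams = cp.CanopyParams()
    growth: bm.GenotypeGrowth = bm.GenotypeGrowth()
    trait: vt.TraitParams | None = None

    def with_trait(self, trait: vt.TraitParams | None) -> "GenotypeBundle":
        return replace(self, trait=trait)


@dataclass(frozen=True)
class SimulationConfig:
    """Management and site configuration.

    The sowing window for the region is April 14 - May 1; the default
    sowing date is April 15.  Density and row spacing follow the standard
    energy-sorghum practice (13.2 plants m-2, 0.76 m rows).  ``n_applied``
    records the nitrogen application for provenance only; nitrogen is
    assumed non-limiting.
    """

    sowing_month_day: tuple[int, int] = (4, 15)
    density: float = 13.2             # plants m-2
    row_spacing: float = 0.76         # m
    season_days: int = 200
    latitude: float = 30.589
    irrigation: sw.IrrigationRegime = sw.IrrigationRegime("none")
    soil_init: str = "dul"            # or "sat"
    svp_fraction: float = 0.75        # daily VPD convention
    twilight_deg: float = wx.DEFAULT_TWILIGHT_DEG  # photoperiod day length
    root_descent: float = 15.0        # mm d-1
    canopy_tt_free: float = 60.0      # DAS before water limits leaf area
    n_applied: float = 100.0          # kg N ha-1, provenance only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density <= 0 or self.season_days <= 0:
            raise ValueError("density and season length must be positive")

    def sowing_date(self, year: int) -> _date:
        return _date(year, *self.sowing_month_day)


OUTPUT_COLUMNS = [
    "das", "date", "stage", "biomass", "lai", "slai", "leaf_no", "height",
    "esw", "rain", "irrigation", "transpiration", "evaporation", "runoff",
    "w_demand", "daily_b", "supply", "soil_water_total", "balance_error",
] + [f"sw_layer{i}" for i in range(1, 7)]


def run_season(
    weather: wx.WeatherSeries,
    year: int,
    config: SimulationConfig = SimulationConfig(),
    genotype: GenotypeBundle = GenotypeBundle(),
    profile: sw.SoilProfile | None = None,
) -> pd.DataFrame:
    """Simulate one season; returns one row per day after sowing.

    The weather series must cover sowing through season end plus one day
    on either side (for the diurnal temperature interpolation).
    """
    profile = profile or sw.default_profile()
    sowing = config.sowing_date(year)
    n_days = config.season_days
    # need day before sowing and day after season end
    series = weather.slice_days(sowing - timedelta(days=1), n_days + 2)
    lat = weather.latitude

    phen = ph.PhenologyState()
    can = cp.CanopyState(leaf_no=genotype.canopy.leaves_at_emergence)
    bio = bm.BiomassState()
    soil = sw.initial_state(profile, config.soil_init)
    geno = genotype
    trait = geno.trait
    hourly_mode_possible = trait is not None and trait.enabled

    rows = []
    prev_water_factor = 1.0
    doys = series.data["date"].dt.dayofyear.to_numpy()

    for das in range(1, n_days + 1):
        i = das  # series index (offset by the lead day)
        today = series.row(i)
        prev = series.row(i - 1)
        nxt = series.row(i + 1)
        doy = int(doys[i])
        water_before = soil.total()

        # --- weather-derived quantities -------------------------------
        photoperiod = wx.day_length(lat, doy, config.twilight_deg)
        sunrise, sunset = wx.sunrise_sunset(lat, doy, 0.0)
        vpd_day = wx.daily_vpd(today.tmax, today.tmin, config.svp_fraction)

        # --- phenology -----------------------------------------------
        tt = ph.daily_thermal_time(
            today.tmax, today.tmin, geno.phenology.cardinal
        )
        phen = ph.advance_phenology(phen, tt, photoperiod, geno.phenology)
        emerged = phen.stage >= ph.Stage.JUVENILE
        pre_fi = phen.stage < ph.Stage.FLORAL_INITIATION

        # --- canopy potential growth ---------------------------------
        if emerged:
            can.leaf_no = cp.leaf_number(
                phen.tt_since_emergence, geno.canopy
            )
            if pre_fi:
                tpla_target = cp.potential_tpla(
                    phen.tt_since_emergence,
                    geno.phenology.tt_emerge_to_fi_base,
                    geno.canopy.leaf_no_max,
                    geno.canopy,
                )
                dtpla = max(tpla_target - can.tpla, 0.0)
                if das > config.canopy_tt_free:
                    dtpla *= prev_water_factor
                can.tpla += dtpla
                can.lai += dtpla * config.density * 1e-4

        # --- radiation-limited biomass -------------------------------
        interception = cp.light_interception(
            can.lai, geno.canopy.extinct_coef
        )
        delta_br = bm.radiation_limited_delta(
            today.radn, interception, geno.growth.rue
        )

        # --- water: hourly VPD sub-model or daily rule ----------------
        soil.root_depth = sw.root_front(das, config.root_descent)
        supply = sw.potential_supply(soil, profile)
        if hourly_mode_possible and can.lai > 0 and delta_br > 0:
            trait_today = trait.effective(das)
            temps = wx.interpolate_hourly_temperature(
                prev, today, nxt, sunrise, sunset
            )
            vpd_hours = wx.hourly_vpd(temps, today.tmin)
            br_hours = vt.hourly_br(delta_br, sunrise, sunset)
            day_result = vt.integrate_day(
                vpd_hours, br_hours, can.lai, geno.growth.te_coef,
                trait_today, supply,
            )
            # unconstrained demand, for the senescence supply:demand ratio
            pot = vt.integrate_day(
                vpd_hours, br_hours, can.lai, geno.growth.te_coef,
                trait_today, float("inf"),
            )
            demand = pot.w_demand
            uptake_wanted = day_result.w_demand
            delta_b = day_result.b
        else:
            demand = bm.daily_water_demand(
                delta_br, vpd_day, geno.growth.te_coef
            )
            uptake_wanted = min(demand, supply)
            delta_b = bm.water_limited_delta(
                uptake_wanted, vpd_day, geno.growth.te_coef, delta_br
            )

        # --- extraction ----------------------------------------------
        uptake, soil = sw.extract(soil, uptake_wanted, profile)

        # --- biomass -------------------------------------------------
        if emerged:
            bio = bm.partition(delta_b, bio, pre_fi, geno.growth)
            stem_per_stem = bio.stem / config.density
            can.height = cp.stem_height(stem_per_stem, geno.canopy)

        # --- senescence ----------------------------------------------
        sd_ratio = supply / demand if demand > 0 else float("inf")
        can = cp.senesce(
            can, min(sd_ratio, 1e6), today.radn, geno.canopy
        )
        prev_water_factor = (
            min(delta_b / delta_br, 1.0) if delta_br > 0 else 1.0
        )

        # --- evaporation, irrigation, infiltration -------------------
        evap, soil = sw.soil_evaporation(soil, today.radn, can.lai, profile)
        irr = sw.irrigation_due(
            soil, config.irrigation, today.date, profile
        )
        runoff_before = soil.cum_runoff
        soil = sw.infiltrate(soil, today.rain + irr, profile)
        soil.cum_rain += today.rain
        soil.cum_irrigation += irr
        runoff_today = soil.cum_runoff - runoff_before

        balance_error = (
            soil.total() - water_before
            - (today.rain + irr)
            + uptake + evap + runoff_today
        )

        rows.append(
            (
                das, today.date, phen.stage.name.lower(), bio.shoot_total,
                can.lai, can.slai, can.leaf_no, can.height,
                sw.extractable_soil_water(soil, profile),
                today.rain, irr, uptake, evap, runoff_today,
                demand, delta_b, supply, soil.total(), balance_error,
                *soil.water_mm,
            )
        )

    out = pd.DataFrame(rows, columns=OUTPUT_COLUMNS)
    out["date"] = pd.to_datetime(out["date"])
    return out


def run_multi_year(
    weather: wx.WeatherSeries,
    config: SimulationConfig = SimulationConfig(),
    genotype: GenotypeBundle = GenotypeBundle(),
    profile: sw.SoilProfile | None = None,
    years: list[int] | None = None,
) -> dict[int, pd.DataFrame]:
    """Independent seasons, profile re-initialized each year.

    Years lacking full weather coverage raise with the year labelled.
    """
    profile = profile or sw.default_profile()
    if years is None:
        years = [
            y for y in weather.years()
            if _covers(weather, config, y)
        ]
    out: dict[int, pd.DataFrame] = {}
    for year in years:
        try:
            out[year] = run_season(weather, year, config, genotype, profile)
        except wx.WeatherError as exc:
            raise wx.WeatherError(f"year {year}: {exc}") from exc
    return out


def _covers(
    weather: wx.WeatherSeries, config: SimulationConfig, year: int
) -> bool:
    first = weather.data["date"].iloc[0].date()
    last = weather.data["date"].iloc[-1].date()
    sowing = config.sowing_date(year)
    return (
        sowing - timedelta(days=1) >= first
        and sowing + timedelta(days=config.season_days + 1) <= last
    )


def season_summary(daily: pd.DataFrame) -> dict[str, float]:
    """End-of-season totals for one simulated season."""
    last = daily.iloc[-1]
    return {
        "biomass_kg_m2": float(last["biomass"]) / 1000.0,
        "water_used_mm": float(
            daily["transpiration"].sum() + daily["evaporation"].sum()
        ),
        "transpiration_mm": float(daily["transpiration"].sum()),
        "rain_mm": float(daily["rain"].sum()),
        "irrigation_mm": float(daily["irrigation"].sum()),
        "peak_lai": float(daily["lai"].max()),
        "final_height_m": float(last["height"]),
    }
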