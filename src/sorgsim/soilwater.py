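"""Layered cascading soil-water bucket with a static water table.

Six layers (0-150, 150-300, 300-600, 600-900, 900-1200, 1200-1500 mm) hold
water between a lower limit (ll) and drained upper limit (dul); infiltration
cascades top-down, and the sixth layer is a water table: roots never enter
it and water reaching it is held rather than drained, so the profile's mass
balance closes exactly.  Root water supply follows the APSIM-style
``kl * (sw - ll)`` extraction from rooted layers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date as _date

import numpy as np

__all__ = [
    "SoilLayer",
    "SoilProfile",
    "SoilWaterState",
    "IrrigationRegime",
    "default_profile",
    "infiltrate",
    "soil_evaporation",
    "root_front",
    "potential_supply",
    "extract",
    "irrigation_due",
]

STANDARD_DEPTHS = ((0, 150), (150, 300), (300, 600), (600, 900),
                   (900, 1200), (1200, 1500))

#: Roots never pass the top of the water-table layer.
MAX_ROOT_DEPTH = 1200.0
SOWING_DEPTH = 50.0


@dataclass(frozen=True)
class SoilLayer:
    top: float      # mm
    bottom: float   # mm
    ll: float       # mm/mm, lower limit of extraction
    dul: float      # mm/mm, drained upper limit
    sat: float      # mm/mm
    kl: float       # d-1, fraction of available water extractable per day

    def __post_init__(self) -> None:
        if not self.ll < self.dul <= self.sat:
            raise ValueError(
                f"layer {self.top}-{self.bottom}: need ll < dul <= sat"
            )
        if not 0.0 <= self.kl <= 1.0:
            raise ValueError(f"kl {self.kl} outside [0, 1]")

    @property
    def thickness(self) -> float:
        return self.bottom - self.top


@dataclass(frozen=True)
class SoilProfile:
    """Exactly six layers; the last one is the impenetrable water table."""

    layers: tuple[SoilLayer, ...]

    def __post_init__(self) -> None:
        prev_bottom = 0.0
        for lay in self.layers:
            if lay.top != prev_bottom:
                raise ValueError("soil layers must be contiguous from 0 mm")
            prev_bottom = lay.bottom
        if len(self.layers) != 6:
            raise ValueError("profile must have exactly 6 layers")

    @property
    def water_table_layer(self) -> int:
        return len(self.layers) - 1

    def arrays(self):
        get = lambda attr: np.array([getattr(l, attr) for l in self.layers])
        return (
            get("top"), get("bottom"), get("ll"), get("dul"),
            get("sat"), get("kl"),
        )


def default_profile() -> SoilProfile:
    """A generic Vertisol-like profile: plant-available water capacity of
    ~219 mm over the rooted 1200 mm."""
    ll = (0.13, 0.15, 0.17, 0.19, 0.20, 0.21)
    dul = (0.32, 0.34, 0.36, 0.37, 0.37, 0.37)
    kl = (0.07, 0.07, 0.05, 0.04, 0.03, 0.0)
    return SoilProfile(
        tuple(
            SoilLayer(top, bot, ll[i], dul[i], dul[i] + 0.05, kl[i])
            for i, (top, bot) in enumerate(STANDARD_DEPTHS)
        )
    )


@dataclass
class SoilWaterState:
    """Per-layer stored water (mm) plus cumulative season fluxes (mm)."""

    water_mm: np.ndarray                  # per layer
    root_depth: float = SOWING_DEPTH
    cum_transpiration: float = 0.0
    cum_evaporation: float = 0.0
    cum_drainage: float = 0.0             # zero here: water table holds it
    cum_runoff: float = 0.0
    cum_rain: float = 0.0
    cum_irrigation: float = 0.0

    def copy(self) -> "SoilWaterState":
        return replace(self, water_mm=self.water_mm.copy())

    def total(self) -> float:
        return float(self.water_mm.sum())


def initial_state(
    profile: SoilProfile, condition: str = "dul"
) -> SoilWaterState:
    """Profile filled to ``dul`` (default) or ``sat`` at sowing."""
    top, bottom, ll, dul, sat, kl = profile.arrays()
    level = dul if condition == "dul" else sat
    return SoilWaterState(water_mm=level * (bottom - top))


@dataclass(frozen=True)
class IrrigationRegime:
    """Irrigation rule: apply ``application`` mm when the rooted-profile
    deficit reaches ``trigger_deficit`` mm.  ``limited`` stops on the cutoff
    date (July 7); ``none`` never irrigates."""

    mode: str = "none"                    # none | limited | unlimited
    trigger_deficit: float = 50.0         # mm
    application: float = 150.0            # mm
    cutoff_month_day: tuple[int, int] = (7, 7)

    def __post_init__(self) -> None:
        if self.mode not in ("none", "limited", "unlimited"):
            raise ValueError(f"unknown irrigation mode {self.mode!r}")
        if self.application <= 0 or self.trigger_deficit <= 0:
            raise ValueError("irrigation amounts must be positive")


def infiltrate(
    state: SoilWaterState, water_in: float, profile: SoilProfile
) -> SoilWaterState:
    """Cascade ``water_in`` mm top-down; fill to dul, hold overflow in the
    water-table layer, and send what the column cannot hold to runoff."""
    if water_in < 0:
        raise ValueError("water_in must be >= 0")
    s = state.copy()
    top, bottom, ll, dul, sat, kl = profile.arrays()
    thick = bottom - top
    dul_mm = dul * thick
    sat_mm = sat * thick
    flow = water_in
    for i in range(len(profile.layers)):
        if flow <= 0:
            break
        room = dul_mm[i] - s.water_mm[i]
        if i == profile.water_table_layer:
            room = sat_mm[i] - s.water_mm[i]  # water table holds to sat
        take = min(max(room, 0.0), flow)
        s.water_mm[i] += take
        flow -= take
    if flow > 0:
        # column full to dul; back-fill toward saturation bottom-up is not
        # modeled -- allow the surface layer up to sat, rest runs off
        room = sat_mm[0] - s.water_mm[0]
        take = min(max(room, 0.0), flow)
        s.water_mm[0] += take
        flow -= take
    s.cum_runoff += flow
    return s


def soil_evaporation(
    state: SoilWaterState,
    radn: float,
    lai: float,
    profile: SoilProfile,
    evap_coef: float = 0.25,
) -> tuple[float, SoilWaterState]:
    """First-stage evaporation from the surface layer, shaded by the canopy.

    Potential evaporation is ``evap_coef * radn * exp(-k lai)`` mm (k = 0.7,
    matching canopy extinction); actual is limited by layer-1 water above
    air-dry (taken as ll here, so evaporation never cuts into subsoil
    storage conventions).
    """
    s = state.copy()
    lay = profile.layers[0]
    avail = max(s.water_mm[0] - lay.ll * lay.thickness, 0.0)
    pot = evap_coef * max(radn, 0.0) * np.exp(-0.7 * max(lai, 0.0))
    e = float(min(pot, avail))
    s.water_mm[0] -= e
    s.cum_evaporation += e
    return e, s


def root_front(das: int, descent_rate: float = 15.0) -> float:
    """Root front depth (mm): descends from sowing depth, capped above the
    water table."""
    if das < 0:
        raise ValueError("das must be >= 0")
    return max(SOWING_DEPTH, min(das * descent_rate, MAX_ROOT_DEPTH))


def _root_fractions(profile: SoilProfile, root_depth: float) -> np.ndarray:
    top, bottom, *_ = profile.arrays()
    frac = np.clip((root_depth - top) / (bottom - top), 0.0, 1.0)
    frac[profile.water_table_layer] = 0.0
    return frac


def potential_supply(
    state: SoilWaterState, profile: SoilProfile
) -> float:
    """Water the root system can extract today (mm d-1): sum over rooted
    layers of kl * (sw - ll), with partial weighting at the root front."""
    return float(_supply_terms(state, profile).sum())


def _supply_terms(state: SoilWaterState, profile: SoilProfile) -> np.ndarray:
    top, bottom, ll, dul, sat, kl = profile.arrays()
    thick = bottom - top
    frac = _root_fractions(profile, state.root_depth)
    avail = np.maximum(state.water_mm - ll * thick, 0.0)
    return kl * avail * frac


def extract(
    state: SoilWaterState, demand: float, profile: SoilProfile
) -> tuple[float, SoilWaterState]:
    """Remove up to ``demand`` mm, proportionally to each layer's supply."""
    if demand < 0:
        raise ValueError("demand must be >= 0")
    terms = _supply_terms(state, profile)
    supply = float(terms.sum())
    uptake = min(demand, supply)
    s = state.copy()
    if uptake > 0 and supply > 0:
        s.water_mm = s.water_mm - terms * (uptake / supply)
    s.cum_transpiration += uptake
    return uptake, s


def rooted_deficit(state: SoilWaterState, profile: SoilProfile) -> float:
    """Water (mm) needed to refill rooted layers to dul."""
    top, bottom, ll, dul, sat, kl = profile.arrays()
    thick = bottom - top
    frac = _root_fractions(profile, state.root_depth)
    return float(
        (np.maximum(dul * thick - state.water_mm, 0.0) * frac).sum()
    )


def irrigation_due(
    state: SoilWaterState,
    regime: IrrigationRegime,
    day: _date,
    profile: SoilProfile,
) -> float:
    """Irrigation to apply today (mm) under the configured regime."""
    if regime.mode == "none":
        return 0.0
    if regime.mode == "limited":
        cutoff = _date(day.year, *regime.cutoff_month_day)
        if day > cutoff:
            return 0.0
    if rooted_deficit(state, profile) >= regime.trigger_deficit:
        return regime.application
    return 0.0


def extractable_soil_water(
    state: SoilWaterState, profile: SoilProfile
) -> float:
    """Plant-extractable water (mm) above ll over the rootable column."""
    top, bottom, ll, dul, sat, kl = profile.arrays()
    thick = bottom - top
    esw = np.maximum(state.water_mm - ll * thick, 0.0)
    esw[profile.water_table_layer] = 0.0
    return float(esw.sum())
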