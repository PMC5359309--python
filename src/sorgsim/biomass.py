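"""Daily biomass accumulation and partitioning.

Biomass is the minimum of a radiation-limited rate (intercepted radiation
times radiation use efficiency, RUE) and a water-limited rate (transpired
water times transpiration efficiency TE = TEc / VPD).  Partitioning is a
fixed leaf/stem split before floral initiation and all-stem afterwards;
stem mass drives plant height.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "GenotypeGrowth",
    "BiomassState",
    "radiation_limited_delta",
    "daily_water_demand",
    "water_limited_delta",
    "partition",
]


@dataclass(frozen=True)
class GenotypeGrowth:
    """Growth coefficients.

    ``te_coef`` (TEc) is the transpiration-efficiency coefficient,
    g biomass m-2 per mm water per kPa of VPD (9 is the sorghum convention:
    0.009 kPa kg kg-1 expressed per ground area, since 1 mm over 1 m2 is
    1 kg of water).  TE on a given day is TEc / VPD.
    """

    rue: float = 2.3            # g MJ-1, juvenile to floral initiation
    te_coef: float = 9.0        # g m-2 mm-1 kPa
    leaf_fraction: float = 0.35  # pre-floral-initiation split; rest to stem

    def __post_init__(self) -> None:
        if self.rue <= 0 or self.te_coef <= 0:
            raise ValueError("rue and te_coef must be positive")
        if not 0.0 <= self.leaf_fraction <= 1.0:
            raise ValueError("leaf_fraction must be in [0, 1]")


@dataclass
class BiomassState:
    shoot_total: float = 0.0   # g m-2
    stem: float = 0.0          # g m-2
    leaf: float = 0.0          # g m-2
    daily_delta: float = 0.0   # g m-2 d-1

    def copy(self) -> "BiomassState":
        return replace(self)


def radiation_limited_delta(
    radn: float, interception: float, rue: float
) -> float:
    """Potential biomass gain (g m-2 d-1) from intercepted radiation."""
    if radn < 0 or interception < 0 or rue < 0:
        raise ValueError("inputs must be >= 0")
    return radn * interception * rue


def daily_water_demand(
    delta_br: float, vpd_daily: float, te_coef: float
) -> float:
    """Water (mm d-1) needed to realize the radiation-limited gain."""
    if vpd_daily < 0:
        raise ValueError("vpd must be >= 0")
    return delta_br * vpd_daily / te_coef


def water_limited_delta(
    uptake: float,
    vpd_daily: float,
    te_coef: float,
    radiation_delta: float,
) -> float:
    """Biomass gain (g m-2 d-1) permitted by actual water uptake.

    TE = TEc / VPD; capped at the radiation-limited rate.  A zero daily VPD
    means demand was zero, so radiation sets the rate.
    """
    if uptake < 0:
        raise ValueError("uptake must be >= 0")
    if vpd_daily <= 0:
        return radiation_delta
    return min(uptake * te_coef / vpd_daily, radiation_delta)


def partition(
    delta: float,
    state: BiomassState,
    pre_floral_initiation: bool,
    growth: GenotypeGrowth,
) -> BiomassState:
    """Allocate today's gain between leaf and stem pools."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    s = state.copy()
    leaf_frac = growth.leaf_fraction if pre_floral_initiation else 0.0
    s.leaf += delta * leaf_frac
    s.stem += delta * (1.0 - leaf_frac)
    s.shoot_total += delta
    s.daily_delta = delta
    return s
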