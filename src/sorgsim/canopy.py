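"""Canopy development: leaf number, TPLA, LAI, interception, height, senescence.

Total plant leaf area (TPLA, cm2 per plant) follows a logistic in thermal
time whose asymptote scales as a power of final leaf number; leaf area index
is TPLA times plant density.  Light interception is Beer's law.  Senescence
has two triggers: a water-stress trigger when the soil supply:demand ratio
falls below a threshold, and a shading trigger when radiation at the canopy
base stays below a critical level for longer than a time constant.  Senesced
area moves from ``lai`` to ``slai`` so total produced area is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import math

__all__ = [
    "CanopyParams",
    "CanopyState",
    "leaf_number",
    "potential_tpla",
    "light_interception",
    "stem_height",
    "senesce",
    "TPLA_SCALE",
]

#: Scaling constant c in TPLAmax = c * final_leaf_no ** gamma (cm2 plant-1).
#: Calibrated once so the default genotype at 13.2 plants m-2 peaks near
#: LAI ~ 5 under unlimited water.
TPLA_SCALE = 0.110


@dataclass(frozen=True)
class CanopyParams:
    """Canopy constants; defaults are the energy-sorghum parameterization."""

    leaf_no_max: float = 50.0
    leaf_app_rate1: float = 50.0       # degC d per leaf
    tpla_prod_coef: float = 0.003      # alpha, (degC d)-1
    main_stem_coef: float = 2.68       # gamma (power on leaf number)
    tpla_inflection_ratio: float = 0.725  # beta
    tpla_scale: float = TPLA_SCALE     # c, cm2 plant-1
    extinct_coef: float = 0.70         # Beer's-law k
    sen_light_time_const: float = 25.0  # days of deep shade before senescence
    sen_radn_crit: float = 0.5         # MJ m-2 at canopy base
    sen_threshold: float = 0.03        # supply:demand ratio triggering stress
    sen_water_rate: float = 0.05       # fraction of LAI lost per stressed day
    x_stem_wt: float = 230.0           # g stem-1 at maximum height
    y_height_max: float = 4.0          # m
    leaves_at_emergence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.tpla_inflection_ratio < 1.0:
            raise ValueError("tpla_inflection_ratio must be in (0, 1)")
        if not 0.0 < self.extinct_coef < 1.5:
            raise ValueError("extinct_coef must be in (0, 1.5)")


@dataclass
class CanopyState:
    lai: float = 0.0      # green leaf area index, m2 m-2
    slai: float = 0.0     # senesced leaf area index
    leaf_no: float = 1.0
    height: float = 0.0   # m
    tpla: float = 0.0     # cm2 plant-1 (green + senesced, produced)
    shade_days: int = 0   # consecutive days of deep shade at canopy base

    def copy(self) -> "CanopyState":
        return replace(self)


def leaf_number(tt_since_emergence: float, params: CanopyParams) -> float:
    """Leaves appeared, capped at the genotype maximum."""
    if tt_since_emergence < 0:
        raise ValueError("thermal time must be >= 0")
    n = params.leaves_at_emergence + tt_since_emergence / params.leaf_app_rate1
    return min(n, params.leaf_no_max)


def tpla_max(final_leaf_no: float, params: CanopyParams) -> float:
    """Asymptotic total plant leaf area, cm2 plant-1."""
    return params.tpla_scale * final_leaf_no**params.main_stem_coef


def potential_tpla(
    cum_tt: float,
    tt_to_fi: float,
    final_leaf_no: float,
    params: CanopyParams,
) -> float:
    """Logistic TPLA (cm2 plant-1) at ``cum_tt`` degC d since emergence.

    Inflection sits at ``tpla_inflection_ratio * tt_to_fi`` where
    ``tt_to_fi`` is the thermal-time span from emergence to floral
    initiation.
    """
    if tt_to_fi <= 0:
        raise ValueError("tt_to_fi must be positive")
    alpha = params.tpla_prod_coef
    mid = params.tpla_inflection_ratio * tt_to_fi
    return tpla_max(final_leaf_no, params) / (
        1.0 + math.exp(-alpha * (cum_tt - mid))
    )


def light_interception(lai: float, k: float) -> float:
    """Beer's-law fraction of radiation intercepted by green leaf."""
    if lai < 0:
        raise ValueError("lai must be >= 0")
    return 1.0 - math.exp(-k * lai)


def stem_height(stem_wt_per_stem: float, params: CanopyParams) -> float:
    """Piecewise-linear height (m): 0 at 0 g, max at ``x_stem_wt`` g/stem."""
    if stem_wt_per_stem < 0:
        raise ValueError("stem weight must be >= 0")
    frac = min(stem_wt_per_stem / params.x_stem_wt, 1.0)
    return frac * params.y_height_max


def senesce(
    canopy: CanopyState,
    supply_demand: float,
    daily_radn: float,
    params: CanopyParams,
) -> CanopyState:
    """Apply one day of senescence; green area lost is moved to ``slai``.

    Water stress: while the soil supply:demand ratio sits below
    ``sen_threshold``, a first-order fraction ``sen_water_rate`` of current
    LAI is lost per day.  Deep shade: when radiation transmitted to the
    canopy base (``radn * exp(-k lai)``) stays below ``sen_radn_crit`` for
    more than ``sen_light_time_const`` consecutive days, the lower-canopy
    area beyond the light-limited depth is shed over the same time constant.
    """
    if supply_demand < 0:
        raise ValueError("supply:demand ratio must be >= 0")
    c = canopy.copy()
    loss = 0.0
    if supply_demand < params.sen_threshold:
        loss += params.sen_water_rate * c.lai

    base_radn = daily_radn * math.exp(-params.extinct_coef * c.lai)
    if base_radn < params.sen_radn_crit and daily_radn > 0:
        c.shade_days += 1
    else:
        c.shade_days = 0
    if c.shade_days > params.sen_light_time_const:
        # LAI above which the base drops into deep shade
        lai_lit = (
            math.log(daily_radn / params.sen_radn_crit) / params.extinct_coef
        )
        excess = max(c.lai - lai_lit, 0.0)
        loss += excess / params.sen_light_time_const

    loss = min(loss, c.lai)
    c.lai -= loss
    c.slai += loss
    return c
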