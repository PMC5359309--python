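"""Hourly VPD-limited transpiration: the breakpoint trait model.

Some sorghum genotypes restrict transpiration once vapor pressure deficit
(VPD) exceeds a breakpoint: the transpiration-rate response to VPD is
piecewise linear, with slope ``m1`` below the breakpoint ``vpd_bp`` and
slope ``m2`` (possibly negative) at and above it.  This module evaluates
that response hourly and integrates, over daylight hours, the realized
transpiration rate

    T(t) = min(Tv(t), Tr(t), soil term)

where ``Tv`` is the VPD-limited rate, ``Tr`` the radiation-limited rate
(the rate needed to realize the hour's radiation-limited biomass share),
and the soil term is the day's remaining extractable supply.  The daily
endpoints handed back to the engine are

    W_demand = lai * sum_t T(t)            (mm, water used)
    B        = lai * TEc * sum_t T(t)/vpd(t)   (g m-2, biomass)

so biomass credit per unit of water is larger in low-VPD hours -- the
mechanism by which breakpoint traits trade slower midday transpiration for
higher water-use efficiency.

Trait slopes are kept in the units of the source gas-exchange assays
(mg H2O m-2 leaf s-1 per kPa); ``ASSAY_TO_MM_PER_H`` converts those rates
to mm h-1 per unit leaf area for comparison with ``Tr``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TraitParams",
    "HourlyFluxes",
    "DailyWaterBiomass",
    "tv",
    "tr",
    "hourly_br",
    "hourly_t",
    "integrate_day",
    "TRAIT_PRESETS",
    "no_breakpoint",
    "ASSAY_TO_MM_PER_H",
    "VPD_FLOOR",
]

#: mg H2O m-2 s-1  ->  mm h-1 per m2 of leaf (1 mm = 1 kg m-2).
ASSAY_TO_MM_PER_H = 3600.0e-6

#: VPD below which transpiration is zero regardless of genotype (kPa).
VPD_OFFSET = 0.25

#: Floor applied to vpd in quotients to avoid dawn blow-ups (kPa).
VPD_FLOOR = 0.01


@dataclass(frozen=True)
class TraitParams:
    """VPD-limited transpiration trait {m1, m2, vpd_bp}.

    Slopes are in assay units (mg m-2 s-1 kPa-1); ``vpd_bp`` in kPa.
    ``enabled=False`` selects the engine's daily water pathway.
    ``induction_das`` switches the trait on only from that day after sowing,
    emulating a mid-season induced trait.
    ``intercept_convention`` is ``"zero_at_quarter"`` (no transpiration at
    or below 0.25 kPa) or ``"printed"`` (a legacy intercept of
    m1*(vpd_bp + 0.25) at the breakpoint).
    """

    m1: float
    m2: float
    vpd_bp: float
    enabled: bool = True
    induction_das: int | None = None
    intercept_convention: str = "zero_at_quarter"

    def __post_init__(self) -> None:
        if self.enabled:
            if self.m1 <= 0:
                raise ValueError("m1 must be positive")
            if self.vpd_bp <= VPD_OFFSET:
                raise ValueError(f"vpd_bp must exceed {VPD_OFFSET} kPa")
        if self.intercept_convention not in ("zero_at_quarter", "printed"):
            raise ValueError(
                f"unknown intercept convention {self.intercept_convention!r}"
            )

    def tv_at_bp(self) -> float:
        if self.intercept_convention == "printed":
            return self.m1 * (self.vpd_bp + VPD_OFFSET)
        return self.m1 * (self.vpd_bp - VPD_OFFSET)

    def effective(self, das: int) -> "TraitParams":
        """Trait in force on day ``das``: before ``induction_das`` the
        breakpoint is absent and the genotype follows its m1 line."""
        if self.induction_das is None or das >= self.induction_das:
            return self
        return replace(self, m2=self.m1, vpd_bp=10.0, induction_das=None)


def no_breakpoint(m1: float) -> TraitParams:
    """A genotype lacking a VPD breakpoint: a single line (m1 = m2)."""
    return TraitParams(m1=m1, m2=m1, vpd_bp=10.0)


#: Genotype presets (gas-exchange literature values).
TRAIT_PRESETS: dict[str, TraitParams] = {
    "bql41": TraitParams(m1=20.26, m2=7.27, vpd_bp=1.17),
    "btx623": TraitParams(m1=56.3, m2=10.4, vpd_bp=2.05),
    "sc803": TraitParams(m1=39.8, m2=-6.1, vpd_bp=2.29),
    "sc35": TraitParams(m1=8.96, m2=-12.49, vpd_bp=2.91),
    "tx436": no_breakpoint(6.62),
}


@dataclass(frozen=True)
class HourlyFluxes:
    """Per-leaf-area transpiration rates for one hour (mm h-1 scale)."""

    tr: float
    tv: float
    t: float


@dataclass(frozen=True)
class DailyWaterBiomass:
    """Daily endpoints of the hourly integration."""

    w_demand: float  # mm d-1 used at ground scale
    b: float         # g m-2 d-1


def tv(vpd_t, p: TraitParams):
    """VPD-limited transpiration rate (assay units), clamped at zero.

    Below the breakpoint: m1 * (vpd - 0.25); at and above it, the line
    continues from the breakpoint value with slope m2.  Continuous at
    ``vpd_bp`` and never negative.
    """
    v = np.asarray(vpd_t, dtype=float)
    if (v < 0).any():
        raise ValueError("vpd must be >= 0")
    below = p.m1 * (v - VPD_OFFSET)
    above = p.tv_at_bp() + p.m2 * (v - p.vpd_bp)
    out = np.maximum(np.where(v < p.vpd_bp, below, above), 0.0)
    return float(out) if out.ndim == 0 else out


def tr(br_t, vpd_t, te_coef: float, lai: float):
    """Radiation-limited transpiration rate, mm h-1 per unit leaf area.

    The water that would realize the hour's radiation-limited biomass share
    ``br_t`` (g m-2 ground h-1) at transpiration efficiency TEc/vpd, spread
    over the leaf area.  Zero when there is no canopy.
    """
    if lai <= 0:
        return np.zeros_like(np.asarray(br_t, dtype=float)) if np.ndim(
            br_t
        ) else 0.0
    out = (
        np.asarray(br_t, dtype=float)
        * np.maximum(np.asarray(vpd_t, dtype=float), VPD_FLOOR)
        / (te_coef * lai)
    )
    return float(out) if np.ndim(out) == 0 else out


def hourly_br(
    delta_br_daily: float, sunrise: float, sunset: float,
    hours: np.ndarray | None = None,
) -> np.ndarray:
    """Split the daily radiation-limited biomass over daylight hours.

    Shares follow a half-sinusoid of solar elevation (peak at solar noon),
    are zero at night, and sum exactly to ``delta_br_daily``.
    """
    if not sunset > sunrise:
        raise ValueError("sunset must follow sunrise")
    if hours is None:
        hours = np.arange(24, dtype=float) + 0.5
    w = np.sin(np.pi * (hours - sunrise) / (sunset - sunrise))
    w = np.where((hours > sunrise) & (hours < sunset), np.maximum(w, 0.0), 0.0)
    total = w.sum()
    if total == 0.0:
        return np.zeros_like(w)
    return delta_br_daily * w / total


def hourly_t(
    tv_t: float, tr_t: float, soil_remaining: float, lai: float
) -> tuple[float, float]:
    """Realized rate for one hour and the soil water left afterwards.

    The soil term converts the remaining ground-area supply (mm) to a
    per-leaf hourly rate; water used this hour (t * lai) is deducted.
    """
    if soil_remaining < 0:
        raise ValueError("soil_remaining must be >= 0")
    if lai <= 0:
        return 0.0, soil_remaining
    t = min(tv_t, tr_t, soil_remaining / lai)
    t = max(t, 0.0)
    return t, soil_remaining - t * lai


def integrate_day(
    vpd_hours: np.ndarray,
    br_hours: np.ndarray,
    lai: float,
    te_coef: float,
    p: TraitParams,
    soil_supply: float,
) -> DailyWaterBiomass:
    """Integrate realized transpiration and biomass over one day.

    ``vpd_hours`` and ``br_hours`` are aligned per-hour arrays (24 values,
    zero ``br`` at night).  Soil water is consumed sequentially from
    sunrise: once cumulative ground-area use reaches ``soil_supply`` the
    crossing hour is taken partially and later hours get nothing.
    """
    if lai <= 0 or soil_supply <= 0:
        return DailyWaterBiomass(0.0, 0.0)
    v = np.maximum(np.asarray(vpd_hours, dtype=float), 0.0)
    br = np.asarray(br_hours, dtype=float)
    tv_mm = tv(v, p) * ASSAY_TO_MM_PER_H
    tr_mm = br * np.maximum(v, VPD_FLOOR) / (te_coef * lai)
    t_unc = np.minimum(tv_mm, tr_mm)
    t_unc = np.where(br > 0.0, np.maximum(t_unc, 0.0), 0.0)
    # sequential soil decrement via cumulative ground-area use
    use = t_unc * lai
    cum = np.cumsum(use)
    t = t_unc.copy()
    over = cum > soil_supply
    if over.any():
        k = int(np.argmax(over))
        prior = cum[k] - use[k]
        t[k] = max(soil_supply - prior, 0.0) / lai
        t[k + 1 :] = 0.0
    w_demand = float(lai * t.sum())
    b = float(lai * te_coef * (t / np.maximum(v, VPD_FLOOR)).sum())
    return DailyWaterBiomass(w_demand, b)
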