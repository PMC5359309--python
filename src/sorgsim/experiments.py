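"""Analysis layer: bootstrap bands, drought classification, trait sweeps.

These routines consume the engine's per-day outputs across years:
multi-year mean trajectories with bootstrap confidence bands, a
sliding-window drought-year classifier, a canopy-divergence rule for
attributing genotype differences to canopy maintenance, genotype
comparisons against a no-breakpoint reference, and productivity landscapes
over the (m2, vpd_bp) trait plane for fixed m1 values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import engine as eng
from . import vpd_transpiration as vt
from . import weather as wx

__all__ = [
    "YearLabel",
    "bootstrap_bands",
    "classify_drought_years",
    "canopy_divergence",
    "trait_sweep",
    "compare_genotypes",
]


def bootstrap_bands(
    trajectories: np.ndarray | pd.DataFrame,
    n_boot: int = 50_000,
    levels: tuple[float, ...] = (0.68, 0.98, 1.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-day mean and bootstrap confidence bands over years.

    ``trajectories`` is years x days.  Bands are percentile intervals of the
    bootstrap distribution of the across-year mean; a level of 1.0 is the
    full bootstrap range (min to max).  Deterministic given ``seed``.
    """
    arr = np.asarray(trajectories, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a 2-D (years x days) array with >= 2 years")
    n_years, n_days = arr.shape
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_years, size=(n_boot, n_years))
    boot_means = arr[idx].mean(axis=1)  # (n_boot, n_days)
    out = {"day": np.arange(1, n_days + 1), "mean": arr.mean(axis=0)}
    for lev in levels:
        tag = f"{round(lev * 100):g}"
        if lev >= 1.0:
            lo, hi = boot_means.min(axis=0), boot_means.max(axis=0)
        else:
            q = (1.0 - lev) / 2.0
            lo, hi = np.quantile(boot_means, [q, 1.0 - q], axis=0)
        out[f"lo{tag}"] = lo
        out[f"hi{tag}"] = hi
    return pd.DataFrame(out)


@dataclass(frozen=True)
class YearLabel:
    year: int
    drought: bool
    seasonal_rain: float  # mm over the season window
    mean_vpd: float       # kPa, daily VPD averaged over the season


def classify_drought_years(
    weather: wx.WeatherSeries,
    config: eng.SimulationConfig = eng.SimulationConfig(),
    window: int = 75,
    centers: tuple[int, int] = (107, 139),
    threshold: float = 1.2,
    years: list[int] | None = None,
) -> list[YearLabel]:
    """Label drought years by mid-season rainfall scarcity.

    A year is a drought year iff any ``window``-day sliding window centered
    on a day-after-sowing within ``centers`` (inclusive) has mean rainfall
    below ``threshold`` mm per day.
    """
    if years is None:
        years = [y for y in weather.years() if eng._covers(weather, config, y)]
    half = window // 2
    labels = []
    for year in years:
        sowing = config.sowing_date(year)
        i0 = weather.index_of(sowing)
        rain = weather.data["rain"].to_numpy()
        tmax = weather.data["tmax"].to_numpy()
        tmin = weather.data["tmin"].to_numpy()
        drought = False
        for c in range(centers[0], centers[1] + 1):
            lo = i0 + c - 1 - half
            hi = i0 + c - 1 + half + 1
            if lo < 0 or hi > len(rain):
                raise wx.WeatherError(
                    f"year {year}: drought window centered DAS {c} exceeds "
                    f"the weather series"
                )
            if rain[lo:hi].mean() < threshold:
                drought = True
                break
        sl = slice(i0, i0 + config.season_days)
        vpds = [
            wx.daily_vpd(tx, tn, config.svp_fraction)
            for tx, tn in zip(tmax[sl], tmin[sl])
        ]
        labels.append(
            YearLabel(
                year, drought, float(rain[sl].sum()), float(np.mean(vpds))
            )
        )
    return labels


def canopy_divergence(
    lai_no_bp: np.ndarray,
    lai_with_bp: np.ndarray,
    from_das: int = 100,
    lai_crit: float = 0.5,
) -> bool:
    """True iff, on any day at or after ``from_das``, the no-breakpoint
    canopy has senesced below ``lai_crit`` while the breakpoint genotype
    maintains a larger canopy."""
    a = np.asarray(lai_no_bp, dtype=float)
    b = np.asarray(lai_with_bp, dtype=float)
    if a.shape != b.shape:
        raise ValueError("trajectories must be aligned")
    tail = slice(from_das - 1, None)
    return bool(np.any((a[tail] < lai_crit) & (b[tail] > a[tail])))


def trait_sweep(
    weather: wx.WeatherSeries,
    m1_values: tuple[float, ...] = (6.62, 20.26, 56.3),
    m2_range: tuple[float, float] = (-12.49, 56.3),
    vpd_bp_range: tuple[float, float] = (1.17, 2.91),
    resolution: int = 25,
    config: eng.SimulationConfig = eng.SimulationConfig(),
    genotype: eng.GenotypeBundle = eng.GenotypeBundle(),
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Productivity landscape: multi-year mean end-of-season biomass
    (kg m-2) for each (m1, m2, vpd_bp) grid cell.

    Returns a long-format frame keyed by (m1, m2, vpd_bp) with columns
    ``biomass_kg_m2`` (multi-year mean) and ``n_years``.  Cells are
    independent runs, so the grid is embarrassingly parallel in principle;
    they are evaluated sequentially here.
    """
    m2s = np.linspace(m2_range[0], m2_range[1], resolution)
    bps = np.linspace(vpd_bp_range[0], vpd_bp_range[1], resolution)
    rows = []
    for m1, m2, bp in itertools.product(m1_values, m2s, bps):
        trait = vt.TraitParams(m1=float(m1), m2=float(m2), vpd_bp=float(bp))
        runs = eng.run_multi_year(
            weather, config, genotype.with_trait(trait), years=years
        )
        ends = [df["biomass"].iloc[-1] / 1000.0 for df in runs.values()]
        rows.append((m1, float(m2), float(bp), float(np.mean(ends)),
                     len(ends)))
    return pd.DataFrame(
        rows, columns=["m1", "m2", "vpd_bp", "biomass_kg_m2", "n_years"]
    )


def compare_genotypes(
    weather: wx.WeatherSeries,
    presets: dict[str, vt.TraitParams] | None = None,
    reference_m1: float = 20.26,
    config: eng.SimulationConfig = eng.SimulationConfig(),
    genotype: eng.GenotypeBundle = eng.GenotypeBundle(),
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Season-end biomass per genotype per year, with the mean difference
    against a no-breakpoint reference (m1 = m2 = ``reference_m1``).

    Returns a long-format frame (genotype, year, biomass_kg_m2,
    diff_vs_reference_kg_m2).
    """
    presets = dict(presets or vt.TRAIT_PRESETS)
    ref_name = "no_breakpoint"
    presets[ref_name] = vt.no_breakpoint(reference_m1)
    records = []
    ref_by_year: dict[int, float] = {}
    for name in [ref_name] + [k for k in presets if k != ref_name]:
        runs = eng.run_multi_year(
            weather, config, genotype.with_trait(presets[name]), years=years
        )
        for year, df in runs.items():
            end = float(df["biomass"].iloc[-1]) / 1000.0
            if name == ref_name:
                ref_by_year[year] = end
            records.append((name, year, end))
    out = pd.DataFrame(records, columns=["genotype", "year", "biomass_kg_m2"])
    out["diff_vs_reference_kg_m2"] = out.apply(
        lambda r: r["biomass_kg_m2"] - ref_by_year[r["year"]], axis=1
    )
    return out
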