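"""YAML configuration loading.

A config file has optional sections ``management``, ``soil``, ``genotype``,
``trait``, ``growth`` and ``weather``.  Genotype keys follow the crop-file
naming convention (photoperiod_crit1, leaf_app_rate1, leaf_no_max, ...);
trait keys are m1, m2, vpd_bp, enabled, induction_das, or ``preset`` naming
one of the shipped genotypes.  Omitted sections fall back to the
energy-sorghum defaults.
"""

from __future__ import annotations

from dataclasses import fields, replace

import yaml

from . import biomass as bm
from . import canopy as cp
from . import engine as eng
from . import phenology as ph
from . import soilwater as sw
from . import vpd_transpiration as vt
from . import weather as wx

__all__ = ["load_config", "Loaded"]


def _take(cls, mapping: dict, **extra):
    names = {f.name for f in fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(
            f"unknown keys for {cls.__name__}: {sorted(unknown)}"
        )
    return cls(**{**mapping, **extra})


class Loaded:
    """Bundle of everything a run needs, resolved from one YAML file."""

    def __init__(self, config, genotype, profile, synth_params):
        self.config: eng.SimulationConfig = config
        self.genotype: eng.GenotypeBundle = genotype
        self.profile: sw.SoilProfile = profile
        self.synth_params: wx.SynthWeatherParams = synth_params


def load_config(path) -> Loaded:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    mgmt = dict(raw.get("management", {}))
    irrigation = sw.IrrigationRegime(mode=mgmt.pop("irrigation", "none"))
    if "sowing_month_day" in mgmt:
        mgmt["sowing_month_day"] = tuple(mgmt["sowing_month_day"])
    config = _take(eng.SimulationConfig, mgmt, irrigation=irrigation)

    geno_raw = dict(raw.get("genotype", {}))
    phen_keys = {f.name for f in fields(ph.GenotypePhenology)}
    can_keys = {f.name for f in fields(cp.CanopyParams)}
    phen = _take(
        ph.GenotypePhenology,
        {k: v for k, v in geno_raw.items() if k in phen_keys},
    )
    canopy = _take(
        cp.CanopyParams,
        {k: v for k, v in geno_raw.items() if k in can_keys},
    )
    leftover = set(geno_raw) - phen_keys - can_keys
    if leftover:
        raise ValueError(f"unknown genotype keys: {sorted(leftover)}")
    growth = _take(bm.GenotypeGrowth, dict(raw.get("growth", {})))

    trait_raw = dict(raw.get("trait", {}))
    trait = None
    if trait_raw:
        preset = trait_raw.pop("preset", None)
        if preset is not None:
            trait = vt.TRAIT_PRESETS[preset.lower()]
            if trait_raw:
                trait = replace(trait, **trait_raw)
        else:
            trait = _take(vt.TraitParams, trait_raw)
    genotype = eng.GenotypeBundle(
        phenology=phen, canopy=canopy, growth=growth, trait=trait
    )

    soil_raw = raw.get("soil")
    if soil_raw:
        layers = tuple(
            sw.SoilLayer(
                top=l["top"], bottom=l["bottom"], ll=l["ll"],
                dul=l["dul"], sat=l.get("sat", l["dul"] + 0.05),
                kl=l["kl"],
            )
            for l in soil_raw["layers"]
        )
        profile = sw.SoilProfile(layers)
    else:
        profile = sw.default_profile()

    synth = _take(wx.SynthWeatherParams, dict(raw.get("weather", {})))
    return Loaded(config, genotype, profile, synth)
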