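"""Tunable configuration: tolerances, score weights, energy couples, registry.

All numeric constants used by the LP battery live here so that a single
YAML file can override them::

    tolerances:
      eps_flux: 1.0e-6
    weights:
      sections: {consistency: 3, annotation: 1, basic: 1, biomass: 1}
      tests: {consistency_stoichiometric: 3}
    registry:
      metabolite: {chebi: "CHEBI:\\d+"}
    energy_metabolites:
      atp: {substrates: {atp: 1, h2o: 1}, products: {adp: 1, pi: 1, h: 1}}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import yaml

__all__ = ["Config", "load_config", "DEFAULT_ENERGY_COUPLES", "DEFAULT_SECTION_WEIGHTS"]

# Dissipation couples keyed by energy metabolite; species are matched by
# compartment-stripped base id (aliases configurable).  NTP hydrolysis
# couples follow ATP + H2O -> ADP + Pi + H; redox couples follow
# reduced -> oxidized + H.
DEFAULT_ENERGY_COUPLES: Dict[str, Dict[str, Dict[str, float]]] = {
    "atp": {"substrates": {"atp": 1, "h2o": 1}, "products": {"adp": 1, "pi": 1, "h": 1}},
    "ctp": {"substrates": {"ctp": 1, "h2o": 1}, "products": {"cdp": 1, "pi": 1, "h": 1}},
    "gtp": {"substrates": {"gtp": 1, "h2o": 1}, "products": {"gdp": 1, "pi": 1, "h": 1}},
    "utp": {"substrates": {"utp": 1, "h2o": 1}, "products": {"udp": 1, "pi": 1, "h": 1}},
    "itp": {"substrates": {"itp": 1, "h2o": 1}, "products": {"idp": 1, "pi": 1, "h": 1}},
    "nadh": {"substrates": {"nadh": 1}, "products": {"nad": 1, "h": 1}},
    "nadph": {"substrates": {"nadph": 1}, "products": {"nadp": 1, "h": 1}},
    "fadh2": {"substrates": {"fadh2": 1}, "products": {"fad": 1, "h": 1}},
    "fmnh2": {"substrates": {"fmnh2": 1}, "products": {"fmn": 1, "h": 1}},
    "q8h2": {"substrates": {"q8h2": 1}, "products": {"q8": 1, "h": 1}},
    "mql8": {"substrates": {"mql8": 1}, "products": {"mqn8": 1, "h": 1}},
    "accoa": {"substrates": {"accoa": 1, "h2o": 1}, "products": {"coa": 1, "ac": 1, "h": 1}},
}

DEFAULT_SECTION_WEIGHTS = {"consistency": 3.0, "annotation": 1.0, "basic": 1.0,
                           "biomass": 1.0, "experimental": 1.0}


@dataclass
class Config:
    # LP tolerances
    big_m: float = 1000.0           # upper bound on conservation masses m
    eps_y: float = 1e-6             # conservation-indicator threshold
    eps_flux: float = 1e-6          # zero-flux tolerance
    eps_growth: float = 1e-6        # growth/no-growth threshold, h^-1
    biomass_tolerance: float = 1e-3  # |weight - 1| tolerance, g/mmol
    open_bound: float = 1000.0      # bound used when opening exchanges

    section_weights: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SECTION_WEIGHTS))
    test_weights: Dict[str, float] = field(default_factory=dict)

    energy_couples: Dict[str, Dict[str, Dict[str, float]]] = field(
        default_factory=lambda: {k: {s: dict(d) for s, d in v.items()}
                                 for k, v in DEFAULT_ENERGY_COUPLES.items()})
    #: base-id aliases, e.g. {"ac": ["ac", "acetate"]}
    energy_aliases: Dict[str, list] = field(default_factory=dict)

    #: per-class namespace -> anchored regex overrides (merged over defaults)
    registry_overrides: Dict[str, Dict[str, str]] = field(default_factory=dict)


def load_config(path: Optional[str]) -> Config:
    """Load a YAML configuration file, falling back to defaults throughout."""
    cfg = Config()
    if path is None:
        return cfg
    with open(path, "r", encoding="utf-8") as handle:
        raw = yaml.safe_load(handle) or {}
    tol = raw.get("tolerances", {})
    for key, attr in (("eps_y", "eps_y"), ("eps_flux", "eps_flux"),
                      ("eps_growth", "eps_growth"), ("big_m", "big_m"),
                      ("biomass_tolerance", "biomass_tolerance"),
                      ("open_bound", "open_bound")):
        if key in tol:
            setattr(cfg, attr, float(tol[key]))
    weights = raw.get("weights", {})
    cfg.section_weights.update({k: float(v) for k, v in weights.get("sections", {}).items()})
    cfg.test_weights.update({k: float(v) for k, v in weights.get("tests", {}).items()})
    for key, couple in raw.get("energy_metabolites", {}).items():
        cfg.energy_couples[key] = {
            "substrates": {k: float(v) for k, v in couple.get("substrates", {}).items()},
            "products": {k: float(v) for k, v in couple.get("products", {}).items()},
        }
    for base, aliases in raw.get("energy_aliases", {}).items():
        cfg.energy_aliases[base] = list(aliases)
    for klass, namespaces in raw.get("registry", {}).items():
        cfg.registry_overrides.setdefault(klass, {}).update(
            {k: str(v) for k, v in namespaces.items()})
    return cfg
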