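"""Biomass battery: detection, weight consistency, growth and precursors.

The biomass pseudo-reaction drains precursor metabolites in experimentally
determined proportions; by community convention its coefficients are
normalized so that one mmol of biomass flux corresponds to one gram of dry
weight, hence the 1 g·mmol⁻¹ consistency check.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import cobra

from . import formula as formula_mod
from .config import Config
from .model import Model, SBO_BIOMASS, is_boundary, strip_compartment_suffix
from .sbml import to_cobra

__all__ = [
    "find_biomass_reactions",
    "biomass_weight",
    "growth_rate",
    "precursor_production",
    "direct_precursors",
]


def find_biomass_reactions(model: Model) -> List[str]:
    """Biomass candidates ordered by detection rule.

    SBO:0000629 tag first, then 'biomass' in the id or name
    (case-insensitive), then objective reactions as a fallback.
    """
    by_sbo = [r.id for r in model.reactions if r.sbo == SBO_BIOMASS]
    by_name = [
        r.id
        for r in model.reactions
        if r.id not in by_sbo and ("biomass" in r.id.lower() or "biomass" in r.name.lower())
    ]
    found = by_sbo + by_name
    if found:
        return found
    return [rid for rid in model.objective]


def biomass_weight(model: Model, reaction_id: str) -> Optional[float]:
    """Biomass weight in g·mmol⁻¹: Σ_substrates |S|·MW/1000 − Σ_products.

    Returns ``None`` (undetermined) when any participant lacks a fully
    specified formula.
    """
    rxn = model.reaction(reaction_id)
    total = 0.0
    for mid, coef in rxn.stoichiometry.items():
        met = model.metabolite(mid)
        if met.formula is None:
            return None
        try:
            parsed = formula_mod.parse_formula(met.formula)
            weight = formula_mod.molecular_weight(parsed)
        except (formula_mod.FormulaError, formula_mod.UndefinedWeightError):
            return None
        total += (-coef) * weight / 1000.0  # substrates contribute positively
    return total


def _apply_medium(cm: "cobra.Model", model: Model, medium: str, config: Config) -> None:
    if medium == "default":
        return
    if medium == "complete":
        for rxn in model.reactions:
            if is_boundary(rxn):
                cm.reactions.get_by_id(rxn.id).lower_bound = -config.open_bound
        return
    raise ValueError(f"unknown medium {medium!r} (expected 'default' or 'complete')")


def growth_rate(
    model: Model,
    medium: str = "default",
    config: Optional[Config] = None,
    biomass_id: Optional[str] = None,
    cobra_model: Optional["cobra.Model"] = None,
) -> float:
    """FBA maximum of the biomass reaction under the medium, in h⁻¹.

    An infeasible LP is reported as zero growth.
    """
    config = config or Config()
    if biomass_id is None:
        candidates = find_biomass_reactions(model)
        if not candidates:
            raise ValueError("no biomass reaction found")
        biomass_id = candidates[0]
    cm = cobra_model if cobra_model is not None else to_cobra(model)
    with cm:
        _apply_medium(cm, model, medium, config)
        cm.objective = cm.reactions.get_by_id(biomass_id)
        solution = cm.optimize()
        if solution.status != "optimal":
            return 0.0
        return float(solution.objective_value)


#: substrates of the growth-associated maintenance couple: their moieties are
#: typically conserved (no de novo route), so an isolated demand can never
#: carry flux even in perfectly healthy models — they are not precursors.
GAM_SUBSTRATES = frozenset({"atp", "h2o"})


def biomass_precursors(model: Model, reaction_id: str) -> List[str]:
    """Biomass substrates excluding the maintenance (ATP hydrolysis) couple."""
    rxn = model.reaction(reaction_id)
    return sorted(
        mid for mid in rxn.substrates
        if strip_compartment_suffix(mid, model.compartments) not in GAM_SUBSTRATES
    )


def precursor_production(
    model: Model,
    reaction_id: str,
    medium: str = "default",
    config: Optional[Config] = None,
    cobra_model: Optional["cobra.Model"] = None,
) -> Dict[str, bool]:
    """Per biomass precursor: can a temporary demand for it carry flux?"""
    config = config or Config()
    cm = cobra_model if cobra_model is not None else to_cobra(model)
    out: Dict[str, bool] = {}
    for mid in biomass_precursors(model, reaction_id):
        with cm:
            _apply_medium(cm, model, medium, config)
            demand = cobra.Reaction("GEMAUDIT_TMP_DEMAND", lower_bound=0.0, upper_bound=config.open_bound)
            cm.add_reactions([demand])
            demand.add_metabolites({cm.metabolites.get_by_id(mid): -1.0})
            cm.objective = demand
            solution = cm.optimize()
            value = solution.objective_value if solution.status == "optimal" else 0.0
            out[mid] = bool(value is not None and value > config.eps_flux)
    return out


def _is_transport(model: Model, rxn) -> bool:
    comps = model.compartments or {m.compartment for m in model.metabolites}
    substrates = {strip_compartment_suffix(m, comps) for m in rxn.substrates}
    products = {strip_compartment_suffix(m, comps) for m in rxn.products}
    return bool(substrates & products)


def direct_precursors(model: Model, reaction_id: str) -> List[str]:
    """Biomass substrates with no internal (non-boundary, non-transport)
    producing reaction — i.e. supplied solely via boundary/transport.

    Informational: such precursors deserve curation review but are not an
    error per se.
    """
    rxn = model.reaction(reaction_id)
    direct = []
    for mid in sorted(rxn.substrates):
        produced = False
        for other in model.reactions:
            if other.id == reaction_id or is_boundary(other) or _is_transport(model, other):
                continue
            coef = other.stoichiometry.get(mid, 0.0)
            if (coef > 0 and other.upper_bound > 0) or (coef < 0 and other.lower_bound < 0):
                produced = True
                break
        if not produced:
            direct.append(mid)
    return direct
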