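"""Stoichiometry battery: conservation, balance, blocked reactions, energy cycles.

Stoichiometric consistency follows the classic LP formulation: a network
is consistent iff there exist strictly positive metabolite masses ``m``
with ``S_intᵀ·m = 0`` over the internal (non-boundary, non-biomass)
reactions.  The certificate LP maximizes the number of metabolites that
can carry positive mass via indicator variables ``y ≤ m`` and flags the
rest as unconserved — exactly the metabolites whose mass any consistent
assignment must set to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import cobra
import numpy as np
from scipy.optimize import linprog

from . import formula as formula_mod
from .biomass import find_biomass_reactions
from .config import Config
from .model import Model, is_boundary, strip_compartment_suffix
from .sbml import to_cobra

__all__ = [
    "ConsistencyCertificate",
    "BalanceReport",
    "ReactionBalance",
    "EnergyCycleResult",
    "find_unconserved_metabolites",
    "check_mass_charge_balance",
    "find_blocked_reactions",
    "find_orphans_and_dead_ends",
    "detect_energy_generating_cycle",
]


@dataclass
class ConsistencyCertificate:
    conserved_mass: Dict[str, float]
    indicator: Dict[str, float]
    unconserved: List[str]

    @property
    def consistent(self) -> bool:
        return not self.unconserved


@dataclass
class ReactionBalance:
    reaction_id: str
    element_imbalance: Dict[str, float] = field(default_factory=dict)
    charge_imbalance: Optional[float] = None
    mass_status: str = "balanced"    # balanced | unbalanced | undetermined
    charge_status: str = "balanced"

    @property
    def status(self) -> str:
        order = {"balanced": 0, "unbalanced": 1, "undetermined": 2}
        worst = max((self.mass_status, self.charge_status), key=lambda s: order[s])
        return worst


@dataclass
class BalanceReport:
    reactions: Dict[str, ReactionBalance]


@dataclass
class EnergyCycleResult:
    energy_metabolite: str
    dissipation_flux: Optional[float]  # None when the couple is absent
    cycle_reactions: List[str] = field(default_factory=list)
    compartment: Optional[str] = None

    def has_cycle(self, eps_flux: float = 1e-6) -> bool:
        return self.dissipation_flux is not None and self.dissipation_flux > eps_flux


def _internal_reactions(model: Model):
    biomass = set(find_biomass_reactions(model))
    return [r for r in model.reactions if not is_boundary(r) and r.id not in biomass]


def find_unconserved_metabolites(model: Model, config: Optional[Config] = None) -> ConsistencyCertificate:
    """Certificate LP: maximize Σ y s.t. S_intᵀ m = 0, y ≤ m, y ∈ [0,1], m ∈ [0,M].

    Metabolites whose indicator stays at zero (``y ≤ ε_y``) are
    unconserved; the model is stoichiometrically consistent iff that set
    is empty.  The LP relaxation (continuous y) is used instead of a MILP;
    the exhaustive oracle in the test suite guards its correctness.
    """
    config = config or Config()
    met_ids = [m.id for m in model.metabolites]
    internal = _internal_reactions(model)
    if not internal or not met_ids:
        return ConsistencyCertificate(
            conserved_mass={m: 1.0 for m in met_ids},
            indicator={m: 1.0 for m in met_ids},
            unconserved=[],
        )
    met_pos = {mid: i for i, mid in enumerate(met_ids)}
    n = len(met_ids)
    # variables: m_0..m_{n-1}, y_0..y_{n-1}
    A_eq = np.zeros((len(internal), 2 * n))
    for row, rxn in enumerate(internal):
        for mid, coef in rxn.stoichiometry.items():
            A_eq[row, met_pos[mid]] = coef
    A_ub = np.hstack([-np.eye(n), np.eye(n)])  # y - m <= 0
    c = np.concatenate([np.zeros(n), -np.ones(n)])
    bounds = [(0.0, config.big_m)] * n + [(0.0, 1.0)] * n
    res = linprog(c, A_eq=A_eq, b_eq=np.zeros(len(internal)),
                  A_ub=A_ub, b_ub=np.zeros(n), bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - m = 0 is always feasible
        raise RuntimeError(f"consistency LP failed: {res.message}")
    m_vals = res.x[:n]
    y_vals = res.x[n:]
    unconserved = sorted(met_ids[i] for i in range(n) if y_vals[i] <= config.eps_y)
    return ConsistencyCertificate(
        conserved_mass=dict(zip(met_ids, map(float, m_vals))),
        indicator=dict(zip(met_ids, map(float, y_vals))),
        unconserved=unconserved,
    )


def check_mass_charge_balance(model: Model) -> BalanceReport:
    """Elemental and charge imbalance of every internal reaction.

    A reaction is undetermined on the element side when any participant
    lacks a fully specified formula, and on the charge side when any
    participant lacks a charge.  Boundary and biomass pseudo-reactions are
    excluded (they move mass across the system boundary by design).
    """
    report: Dict[str, ReactionBalance] = {}
    met_index = {m.id: m for m in model.metabolites}
    for rxn in _internal_reactions(model):
        balance = ReactionBalance(reaction_id=rxn.id)
        elements: Dict[str, float] = {}
        undetermined_mass = False
        for mid, coef in rxn.stoichiometry.items():
            met = met_index[mid]
            if met.formula is None:
                undetermined_mass = True
                continue
            try:
                parsed = formula_mod.parse_formula(met.formula)
            except formula_mod.FormulaError:
                undetermined_mass = True
                continue
            if not parsed.is_fully_specified:
                undetermined_mass = True
                continue
            for element, count in parsed.counts.items():
                elements[element] = elements.get(element, 0.0) + coef * count
        elements = {e: v for e, v in elements.items() if abs(v) > 1e-9}
        if undetermined_mass:
            balance.mass_status = "undetermined"
        else:
            balance.element_imbalance = elements
            balance.mass_status = "unbalanced" if elements else "balanced"
        if any(met_index[mid].charge is None for mid in rxn.stoichiometry):
            balance.charge_status = "undetermined"
        else:
            net = sum(coef * met_index[mid].charge for mid, coef in rxn.stoichiometry.items())
            balance.charge_imbalance = float(net)
            balance.charge_status = "unbalanced" if abs(net) > 1e-9 else "balanced"
        report[rxn.id] = balance
    return BalanceReport(reactions=report)


def find_blocked_reactions(model: Model, config: Optional[Config] = None,
                           cobra_model: Optional["cobra.Model"] = None) -> List[str]:
    """Permanently blocked reactions under the most permissive medium.

    All boundary reactions are opened to ±open_bound, then flux
    variability analysis marks a reaction blocked iff its flux range is
    within ``eps_flux`` of zero in both directions.
    """
    config = config or Config()
    if not model.reactions:
        return []
    cm = cobra_model if cobra_model is not None else to_cobra(model)
    with cm:
        for rxn in model.reactions:
            if is_boundary(rxn):
                crxn = cm.reactions.get_by_id(rxn.id)
                crxn.bounds = (-config.open_bound, config.open_bound)
        fva = cobra.flux_analysis.flux_variability_analysis(
            cm, fraction_of_optimum=0.0, processes=1)
    blocked = [
        rid
        for rid in fva.index
        if abs(fva.at[rid, "minimum"]) <= config.eps_flux
        and abs(fva.at[rid, "maximum"]) <= config.eps_flux
    ]
    return sorted(blocked)


def find_orphans_and_dead_ends(model: Model) -> Tuple[List[str], List[str]]:
    """Topological orphan/dead-end detection honoring reaction reversibility.

    Orphan: never appears as a net product of any non-boundary reaction in
    an allowed direction.  Dead end: symmetric for consumption.
    """
    producible, consumable = set(), set()
    for rxn in model.reactions:
        if is_boundary(rxn):
            continue
        for mid, coef in rxn.stoichiometry.items():
            if coef > 0:
                if rxn.upper_bound > 0:
                    producible.add(mid)
                if rxn.lower_bound < 0:
                    consumable.add(mid)
            elif coef < 0:
                if rxn.upper_bound > 0:
                    consumable.add(mid)
                if rxn.lower_bound < 0:
                    producible.add(mid)
    orphans = sorted(m.id for m in model.metabolites if m.id not in producible)
    dead_ends = sorted(m.id for m in model.metabolites if m.id not in consumable)
    return orphans, dead_ends


def _match_energy_species(model: Model, base_ids: List[str], config: Config) -> Optional[Dict[str, Dict[str, str]]]:
    """Map each base id to a concrete metabolite per compartment; pick a
    compartment hosting all of them (preferring cytosol-like 'c')."""
    comps = model.compartments or sorted({m.compartment for m in model.metabolites})
    aliases = {base: set([base] + list(config.energy_aliases.get(base, []))) for base in base_ids}
    per_comp: Dict[str, Dict[str, str]] = {}
    for met in model.metabolites:
        base = strip_compartment_suffix(met.id, comps)
        for want, names in aliases.items():
            if base in names:
                per_comp.setdefault(met.compartment, {})[want] = met.id
    candidates = [c for c, found in per_comp.items() if len(found) == len(base_ids)]
    if not candidates:
        return None
    chosen = "c" if "c" in candidates else sorted(candidates)[0]
    return {"compartment": chosen, "mapping": per_comp[chosen]}


def detect_energy_generating_cycle(
    model: Model,
    energy_metabolite: str,
    config: Optional[Config] = None,
    cobra_model: Optional["cobra.Model"] = None,
) -> EnergyCycleResult:
    """Detect production of an energy currency from nothing.

    All boundary reactions are closed, a temporary dissipation reaction
    for the requested couple (e.g. atp + h2o → adp + pi + h) is added and
    its flux maximized; any optimum above tolerance certifies an
    energy-generating cycle, whose member reactions are reported.
    """
    config = config or Config()
    couple = config.energy_couples.get(energy_metabolite)
    if couple is None:
        raise KeyError(f"unknown energy metabolite key {energy_metabolite!r}")
    base_ids = list(couple["substrates"]) + list(couple["products"])
    match = _match_energy_species(model, base_ids, config)
    if match is None:
        return EnergyCycleResult(energy_metabolite=energy_metabolite, dissipation_flux=None)
    mapping = match["mapping"]
    cm = cobra_model if cobra_model is not None else to_cobra(model)
    with cm:
        for rxn in model.reactions:
            if is_boundary(rxn):
                cm.reactions.get_by_id(rxn.id).bounds = (0.0, 0.0)
        dissipation = cobra.Reaction("GEMAUDIT_DISSIPATION",
                                     lower_bound=0.0, upper_bound=config.open_bound)
        cm.add_reactions([dissipation])
        stoich = {}
        for base, coef in couple["substrates"].items():
            stoich[cm.metabolites.get_by_id(mapping[base])] = -float(coef)
        for base, coef in couple["products"].items():
            met = cm.metabolites.get_by_id(mapping[base])
            stoich[met] = stoich.get(met, 0.0) + float(coef)
        dissipation.add_metabolites(stoich)
        cm.objective = dissipation
        solution = cm.optimize()
        if solution.status != "optimal":
            flux, cycle = 0.0, []
        else:
            flux = float(solution.objective_value)
            cycle = sorted(
                rid
                for rid, value in solution.fluxes.items()
                if rid != "GEMAUDIT_DISSIPATION" and abs(value) > config.eps_flux
            ) if flux > config.eps_flux else []
    return EnergyCycleResult(
        energy_metabolite=energy_metabolite,
        dissipation_flux=flux,
        cycle_reactions=cycle,
        compartment=match["compartment"],
    )
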