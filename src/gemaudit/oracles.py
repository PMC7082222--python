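"""Brute-force LP oracles used for fixture ground truth and cross-checks.

Everything here is deliberately naive and solver-independent from the main
battery: plain dense matrices and :func:`scipy.optimize.linprog` (HiGHS),
one small LP per question.  The fixture generator freezes these answers
into its manifest, and the test suite compares the production code paths
(cobra/optlang based) against them.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import linprog

from . import gpr as gpr_mod
from .model import Model, Reaction, is_boundary

__all__ = [
    "stoichiometric_matrix",
    "internal_reaction_ids",
    "fba_oracle",
    "fva_blocked_oracle",
    "unconserved_per_met_oracle",
    "unconserved_subset_oracle",
    "single_knockout_oracle",
]


def _biomass_like(model: Model) -> Set[str]:
    from .biomass import find_biomass_reactions

    return set(find_biomass_reactions(model))


def stoichiometric_matrix(
    model: Model, reaction_ids: Optional[Sequence[str]] = None
) -> Tuple[np.ndarray, List[str], List[str]]:
    """Dense S (metabolites x reactions) plus row/column id orderings."""
    met_ids = [m.id for m in model.metabolites]
    met_pos = {mid: i for i, mid in enumerate(met_ids)}
    if reaction_ids is None:
        reaction_ids = [r.id for r in model.reactions]
    rxn_index = {r.id: r for r in model.reactions}
    S = np.zeros((len(met_ids), len(reaction_ids)))
    for j, rid in enumerate(reaction_ids):
        for mid, coef in rxn_index[rid].stoichiometry.items():
            S[met_pos[mid], j] = coef
    return S, met_ids, list(reaction_ids)


def internal_reaction_ids(model: Model) -> List[str]:
    """Reactions entering the conservation analysis: neither boundary nor biomass."""
    biomass = _biomass_like(model)
    return [r.id for r in model.reactions if not is_boundary(r) and r.id not in biomass]


def _bounds(model: Model, override: Optional[Dict[str, Tuple[float, float]]] = None):
    bounds = {}
    for rxn in model.reactions:
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if override and rxn.id in override:
            lb, ub = override[rxn.id]
        bounds[rxn.id] = (lb, ub)
    return bounds


def fba_oracle(
    model: Model,
    objective: Dict[str, float],
    bound_override: Optional[Dict[str, Tuple[float, float]]] = None,
) -> Tuple[Optional[float], Dict[str, float]]:
    """Maximize a linear flux objective subject to S v = 0 and bounds.

    Returns ``(optimum, flux_by_reaction)``; optimum is ``None`` when the
    LP is infeasible.
    """
    S, _, rxn_ids = stoichiometric_matrix(model)
    bounds = _bounds(model, bound_override)
    c = np.zeros(len(rxn_ids))
    for rid, weight in objective.items():
        c[rxn_ids.index(rid)] = -weight  # linprog minimizes
    res = linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]),
        bounds=[bounds[r] for r in rxn_ids], method="highs",
    )
    if not res.success:
        return None, {}
    return -res.fun, dict(zip(rxn_ids, res.x))


def fva_blocked_oracle(model: Model, eps_flux: float = 1e-6,
                       open_bound: float = 1000.0) -> List[str]:
    """Blocked reactions by the definitional two-LP flux-variability scan.

    All boundary reactions are opened to ±open_bound first (the most
    permissive medium) and each reaction is minimized and maximized in
    turn; a reaction is blocked iff both extrema are within tolerance of
    zero.
    """
    override = {r.id: (-open_bound, open_bound) for r in model.reactions if is_boundary(r)}
    S, _, rxn_ids = stoichiometric_matrix(model)
    bounds = _bounds(model, override)
    blocked = []
    box = [bounds[r] for r in rxn_ids]
    for j, rid in enumerate(rxn_ids):
        c = np.zeros(len(rxn_ids))
        c[j] = 1.0
        lo = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=box, method="highs")
        hi = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=box, method="highs")
        vmin = lo.fun if lo.success else 0.0
        vmax = -hi.fun if hi.success else 0.0
        if abs(vmin) <= eps_flux and abs(vmax) <= eps_flux:
            blocked.append(rid)
    return sorted(blocked)


def _internal_matrix(model: Model):
    rxn_ids = internal_reaction_ids(model)
    S, met_ids, _ = stoichiometric_matrix(model, rxn_ids)
    return S, met_ids


def unconserved_per_met_oracle(model: Model, big_m: float = 1000.0,
                               eps: float = 1e-9) -> List[str]:
    """Unconserved metabolites, one feasibility LP per metabolite.

    Metabolite i is conserved iff max m_i subject to S_intᵀ m = 0,
    0 ≤ m ≤ M is strictly positive.
    """
    S, met_ids = _internal_matrix(model)
    if S.shape[1] == 0:
        return []
    A_eq = S.T  # one row per internal reaction
    unconserved = []
    for i, mid in enumerate(met_ids):
        c = np.zeros(len(met_ids))
        c[i] = -1.0
        res = linprog(c, A_eq=A_eq, b_eq=np.zeros(A_eq.shape[0]),
                      bounds=[(0.0, big_m)] * len(met_ids), method="highs")
        best = -res.fun if res.success else 0.0
        if best <= eps:
            unconserved.append(mid)
    return sorted(unconserved)


def unconserved_subset_oracle(model: Model, big_m: float = 1000.0) -> List[str]:
    """Exhaustive subset-feasibility oracle (tiny networks only).

    For every subset T of metabolites, check feasibility of
    {S_intᵀ m = 0, m_i ≥ 1 on T, 0 ≤ m ≤ M}; the union of all feasible
    subsets is the conserved set and its complement is returned.
    Exponential in the metabolite count by design.
    """
    S, met_ids = _internal_matrix(model)
    n = len(met_ids)
    if n > 16:
        raise ValueError("subset oracle is exponential; refusing n > 16 metabolites")
    if S.shape[1] == 0:
        return []
    A_eq = S.T
    conserved: Set[str] = set()
    zero = np.zeros(A_eq.shape[0])
    for size in range(1, n + 1):
        for subset in combinations(range(n), size):
            if all(met_ids[i] in conserved for i in subset):
                continue
            bounds = [(1.0, big_m) if i in subset else (0.0, big_m) for i in range(n)]
            res = linprog(np.zeros(n), A_eq=A_eq, b_eq=zero, bounds=bounds, method="highs")
            if res.success:
                conserved.update(met_ids[i] for i in subset)
    return sorted(set(met_ids) - conserved)


def single_knockout_oracle(model: Model, objective_id: str,
                           eps_growth: float = 1e-6) -> Set[str]:
    """Essential genes by exhaustive single-knockout FBA.

    A gene is essential iff disabling every reaction whose GPR evaluates
    false without it drops the objective optimum below ``eps_growth``.
    """
    trees = {}
    for rxn in model.reactions:
        if rxn.gpr:
            trees[rxn.id] = gpr_mod.parse_gpr(rxn.gpr)
    essential = set()
    for gene in model.genes:
        knocked = {gene.id}
        override = {
            rid: (0.0, 0.0)
            for rid, tree in trees.items()
            if not gpr_mod.eval_gpr(tree, knocked)
        }
        optimum, _ = fba_oracle(model, {objective_id: 1.0}, override)
        if optimum is None or optimum < eps_growth:
            essential.add(gene.id)
    return essential
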