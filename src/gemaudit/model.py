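"""In-memory representation of a constraint-based metabolic model.

Every QC test in this package consumes the lightweight containers defined
here rather than a solver-bound object.  The stoichiometric convention is
the usual one: for reaction ``j`` and metabolite ``i`` the coefficient
``S[i, j]`` is negative for substrates and positive for products; flux
bounds are in mmol·gDW⁻¹·h⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

__all__ = [
    "Metabolite",
    "Reaction",
    "Gene",
    "Model",
    "StructuralIssue",
    "StructuralError",
    "is_boundary",
    "boundary_kind",
    "strip_compartment_suffix",
]

#: SBO terms that mark boundary pseudo-reactions.
SBO_EXCHANGE = "SBO:0000627"
SBO_DEMAND = "SBO:0000628"
SBO_SINK = "SBO:0000632"
SBO_BIOMASS = "SBO:0000629"
SBO_METABOLIC_REACTION = "SBO:0000176"
SBO_METABOLITE = "SBO:0000247"
SBO_GENE = "SBO:0000243"

_BOUNDARY_SBO = {SBO_EXCHANGE, SBO_DEMAND, SBO_SINK}
_BOUNDARY_PREFIXES = (("ex_", "exchange"), ("dm_", "demand"), ("sk_", "sink"))


class StructuralError(Exception):
    """Raised when a document cannot be mapped onto :class:`Model` at all."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: Optional[str] = None
    charge: Optional[int] = None
    annotations: Dict[str, List[str]] = field(default_factory=dict)
    sbo: Optional[str] = None

    def copy(self) -> "Metabolite":
        return replace(self, annotations={k: list(v) for k, v in self.annotations.items()})


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gpr: Optional[str] = None
    annotations: Dict[str, List[str]] = field(default_factory=dict)
    sbo: Optional[str] = None

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def substrates(self) -> List[str]:
        return [m for m, c in self.stoichiometry.items() if c < 0]

    @property
    def products(self) -> List[str]:
        return [m for m, c in self.stoichiometry.items() if c > 0]

    def copy(self) -> "Reaction":
        return replace(
            self,
            stoichiometry=dict(self.stoichiometry),
            annotations={k: list(v) for k, v in self.annotations.items()},
        )


@dataclass
class Gene:
    id: str
    name: str = ""
    annotations: Dict[str, List[str]] = field(default_factory=dict)
    sbo: Optional[str] = None

    def copy(self) -> "Gene":
        return replace(self, annotations={k: list(v) for k, v in self.annotations.items()})


@dataclass
class StructuralIssue:
    severity: str  # "error" | "warning"
    code: str
    message: str
    element_id: Optional[str] = None


@dataclass
class Model:
    id: str
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    genes: List[Gene] = field(default_factory=list)
    compartments: Dict[str, str] = field(default_factory=dict)
    objective: Dict[str, float] = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------
    def metabolite(self, mid: str) -> Metabolite:
        return self._met_index()[mid]

    def reaction(self, rid: str) -> Reaction:
        return self._rxn_index()[rid]

    def _met_index(self) -> Dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    def _rxn_index(self) -> Dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def copy(self) -> "Model":
        return Model(
            id=self.id,
            metabolites=[m.copy() for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            genes=[g.copy() for g in self.genes],
            compartments=dict(self.compartments),
            objective=dict(self.objective),
        )

    def check_integrity(self) -> List[str]:
        """Return human-readable referential-integrity violations, if any."""
        problems = []
        mids = [m.id for m in self.metabolites]
        if len(set(mids)) != len(mids):
            problems.append("duplicate metabolite ids")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            problems.append("duplicate reaction ids")
        known = set(mids)
        for rxn in self.reactions:
            for mid in rxn.stoichiometry:
                if mid not in known:
                    problems.append(f"reaction {rxn.id} references unknown metabolite {mid}")
            if rxn.lower_bound > rxn.upper_bound:
                problems.append(f"reaction {rxn.id} has lower_bound > upper_bound")
        for met in self.metabolites:
            if met.compartment and met.compartment not in self.compartments:
                problems.append(f"metabolite {met.id} in undeclared compartment {met.compartment}")
        for rid in self.objective:
            if rid not in set(rids):
                problems.append(f"objective references unknown reaction {rid}")
        return problems


def boundary_kind(reaction: Reaction) -> Optional[str]:
    """Classify a boundary pseudo-reaction as exchange/demand/sink.

    Detection rules, first match wins: SBO term (627/628/632), then the
    single-metabolite criterion, then the EX_/DM_/SK_ id prefix
    (case-insensitive).  Returns ``None`` for internal reactions.
    """
    if reaction.sbo in _BOUNDARY_SBO:
        return {SBO_EXCHANGE: "exchange", SBO_DEMAND: "demand", SBO_SINK: "sink"}[reaction.sbo]
    low = reaction.id.lower()
    if len(reaction.stoichiometry) == 1:
        for prefix, kind in _BOUNDARY_PREFIXES:
            if low.startswith(prefix):
                return kind
        # single-metabolite reactions default to exchange semantics
        return "exchange"
    for prefix, kind in _BOUNDARY_PREFIXES:
        if low.startswith(prefix):
            return kind
    return None


def is_boundary(reaction: Reaction) -> bool:
    return boundary_kind(reaction) is not None


def strip_compartment_suffix(met_id: str, compartments) -> str:
    """Remove a trailing ``_<compartment-id>`` from a metabolite id."""
    for comp in sorted(compartments, key=len, reverse=True):
        if comp and met_id.endswith("_" + comp):
            return met_id[: -(len(comp) + 1)]
    return met_id
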