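"""Deterministic toy-model generator with plantable, manifest-tracked defects.

The textbook fixture is a ~20-metabolite, ~19-reaction aerobic toy cell:
glucose uptake → lumped glycolysis → respiration-driven ATP synthesis →
alanine synthesis → a biomass drain normalized to exactly 1 g·mmol⁻¹.
Every reaction is elementally and charge balanced, every component fully
annotated (cross-references + SBO), every non-boundary reaction carries a
GPR, and the network is stoichiometrically consistent, energy-cycle-free
and free of blocked reactions, orphans and dead ends — verified at build
time by the brute-force oracles, whose answers are frozen into the
fixture manifest.

:func:`plant_defect` returns a modified copy plus an updated manifest that
names the tests expected to degrade and the offending element ids; the
expectations for LP-derived sets (unconserved metabolites, blocked
reactions, orphans/dead ends, growth collapse) come from re-running the
oracles, never from the production code paths under test.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import yaml

from . import oracles
from .formula import molecular_weight, parse_formula
from .model import (
    Gene,
    Metabolite,
    Model,
    Reaction,
    SBO_BIOMASS,
    SBO_EXCHANGE,
    SBO_GENE,
    SBO_METABOLIC_REACTION,
    SBO_METABOLITE,
    is_boundary,
)

__all__ = ["FixtureManifest", "make_textbook_model", "plant_defect",
           "make_random_network", "DEFECT_KINDS"]

BIOMASS_ID = "BIOMASS"

DEFECT_KINDS = (
    "unconserved_metabolite",
    "unbalanced_reaction",
    "energy_generating_cycle",
    "blocked_subnetwork",
    "orphan_metabolite",
    "dead_end_metabolite",
    "strip_gpr",
    "strip_formula",
    "strip_charge",
    "strip_annotations",
    "strip_sbo",
    "break_biomass_weight",
    "remove_precursor_path",
)


@dataclass
class FixtureManifest:
    model_id: str
    seed: int
    planted_defects: List[dict] = field(default_factory=list)
    ground_truth: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "seed": self.seed,
            "planted_defects": self.planted_defects,
            "ground_truth": self.ground_truth,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @property
    def expected_degraded_tests(self) -> Set[str]:
        out: Set[str] = set()
        for defect in self.planted_defects:
            out |= set(defect["degraded_tests"])
        return out

    @property
    def expected_offenders(self) -> Dict[str, Set[str]]:
        out: Dict[str, Set[str]] = {}
        for defect in self.planted_defects:
            for test_id, ids in defect["offenders"].items():
                out.setdefault(test_id, set()).update(ids)
        return out


# --------------------------------------------------------------------------
# annotation synthesis (pattern-valid synthetic identifiers)

def _inchikey(rng: random.Random) -> str:
    letters = string.ascii_uppercase
    return ("".join(rng.choice(letters) for _ in range(14)) + "-"
            + "".join(rng.choice(letters) for _ in range(10)) + "-N")


def _met_annotations(base: str, index: int, rng: random.Random) -> Dict[str, List[str]]:
    return {
        "kegg.compound": [f"C{10000 + index:05d}"],
        "chebi": [f"CHEBI:{1000 + index}"],
        "metanetx.chemical": [f"MNXM{100 + index}"],
        "bigg.metabolite": [base],
        "seed.compound": [f"cpd{index:05d}"],
        "inchikey": [_inchikey(rng)],
        "hmdb": [f"HMDB{index:07d}"],
        "pubchem.compound": [str(100 + index)],
    }


def _rxn_annotations(rxn_id: str, index: int) -> Dict[str, List[str]]:
    return {
        "rhea": [f"{10000 + index}"],
        "kegg.reaction": [f"R{index:05d}"],
        "metanetx.reaction": [f"MNXR{100 + index}"],
        "bigg.reaction": [rxn_id],
        "ec-code": [f"{1 + index % 6}.{1 + index % 9}.{1 + index % 9}.{1 + index % 30}"],
        "seed.reaction": [f"rxn{index:05d}"],
        "biocyc": [f"META:RXN-{index}"],
    }


def _gene_annotations(gene_id: str, index: int) -> Dict[str, List[str]]:
    return {
        "refseq": [f"NP_{414000 + index:06d}"],
        "uniprot": [gene_id],
        "ncbigene": [str(944000 + index)],
        "kegg.genes": [f"eco:b{index:04d}"],
    }


# --------------------------------------------------------------------------
# the healthy textbook network

_SPECIES = [
    # base, compartments, formula, charge, name
    ("glc", ("e", "c"), "C6H12O6", 0, "D-glucose"),
    ("o2", ("e", "c"), "O2", 0, "oxygen"),
    ("nh4", ("e", "c"), "H4N", 1, "ammonium"),
    ("pi", ("e", "c"), "HO4P", -2, "phosphate"),
    ("h2o", ("e", "c"), "H2O", 0, "water"),
    ("h", ("e", "c"), "H", 1, "proton"),
    ("pyr", ("e", "c"), "C3H3O3", -1, "pyruvate"),
    ("g6p", ("c",), "C6H11O9P", -2, "glucose 6-phosphate"),
    ("atp", ("c",), "C10H12N5O13P3", -4, "ATP"),
    ("adp", ("c",), "C10H12N5O10P2", -3, "ADP"),
    ("nad", ("c",), "C21H26N7O14P2", -1, "NAD+"),
    ("nadh", ("c",), "C21H27N7O14P2", -2, "NADH"),
    ("ala__L", ("c",), "C3H7NO2", 0, "L-alanine"),
]

_GAM = 30.0  # growth-associated maintenance, mmol ATP per g biomass


def make_textbook_model(seed: int = 0) -> Tuple[Model, FixtureManifest]:
    """Build the healthy textbook fixture and its oracle-verified manifest."""
    rng = random.Random(seed)
    model = Model(id=f"textbook_{seed}",
                  compartments={"c": "cytosol", "e": "extracellular space"})
    index = 0
    for base, comps, formula, charge, name in _SPECIES:
        for comp in comps:
            index += 1
            model.metabolites.append(Metabolite(
                id=f"{base}_{comp}", name=name, compartment=comp,
                formula=formula, charge=charge,
                annotations=_met_annotations(base, index, rng),
                sbo=SBO_METABOLITE,
            ))

    genes = {
        "GLCt": "P10001", "O2t": "P10002", "NH4t": "P10003", "PIt": "P10004",
        "H2Ot": "P10005", "Ht": "P10006", "PYRt": "P10007", "HEX1": "P10008",
        "RESP": "P10011 and P10012", "ALATA": "P10013", BIOMASS_ID: "P10014",
        "GLYC": "P10009 or P10010",
    }

    rxn_index = 0

    def add_reaction(rid, name, stoich, lb, ub, gpr=None, sbo=SBO_METABOLIC_REACTION):
        nonlocal rxn_index
        rxn_index += 1
        model.reactions.append(Reaction(
            id=rid, name=name, stoichiometry=dict(stoich),
            lower_bound=lb, upper_bound=ub, gpr=gpr,
            annotations=_rxn_annotations(rid, rxn_index), sbo=sbo,
        ))

    # exchanges (negative flux = uptake)
    for base, lb in (("glc", -10.0), ("o2", -1000.0), ("nh4", -1000.0),
                     ("pi", -1000.0), ("h2o", -1000.0), ("h", -1000.0),
                     ("pyr", 0.0)):
        add_reaction(f"EX_{base}_e", f"{base} exchange", {f"{base}_e": -1.0},
                     lb, 1000.0, sbo=SBO_EXCHANGE)
    # reversible transporters
    for base in ("glc", "o2", "nh4", "pi", "h2o", "h", "pyr"):
        rid = f"{base.upper()[:3]}t" if base != "h2o" else "H2Ot"
        rid = {"glc": "GLCt", "o2": "O2t", "nh4": "NH4t", "pi": "PIt",
               "h2o": "H2Ot", "h": "Ht", "pyr": "PYRt"}[base]
        add_reaction(rid, f"{base} transport", {f"{base}_e": -1.0, f"{base}_c": 1.0},
                     -1000.0, 1000.0, gpr=genes[rid])
    # core metabolism (all elementally and charge balanced)
    add_reaction("HEX1", "hexokinase",
                 {"glc_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1, "h_c": 1},
                 0.0, 1000.0, gpr=genes["HEX1"])
    add_reaction("GLYC", "glycolysis (lumped)",
                 {"g6p_c": -1, "adp_c": -3, "pi_c": -2, "nad_c": -2,
                  "pyr_c": 2, "atp_c": 3, "nadh_c": 2, "h2o_c": 2, "h_c": 1},
                 0.0, 1000.0, gpr=genes["GLYC"])
    add_reaction("RESP", "respiration + oxidative phosphorylation (lumped)",
                 {"nadh_c": -2, "o2_c": -1, "h_c": -6, "adp_c": -4, "pi_c": -4,
                  "nad_c": 2, "atp_c": 4, "h2o_c": 6},
                 0.0, 1000.0, gpr=genes["RESP"])
    add_reaction("ALATA", "alanine synthesis (lumped)",
                 {"pyr_c": -1, "nh4_c": -1, "nadh_c": -1, "h_c": -1,
                  "ala__L_c": 1, "nad_c": 1, "h2o_c": 1},
                 0.0, 1000.0, gpr=genes["ALATA"])
    # biomass: coefficients normalized so the drain weighs 1 g per mmol flux
    mw_ala = molecular_weight(parse_formula("C3H7NO2"))
    mw_g6p = molecular_weight(parse_formula("C6H11O9P"))
    c_g6p = 0.5
    c_ala = (1000.0 - c_g6p * mw_g6p) / mw_ala
    add_reaction(BIOMASS_ID, "biomass (1 g per mmol)",
                 {"ala__L_c": -c_ala, "g6p_c": -c_g6p,
                  "atp_c": -_GAM, "h2o_c": -_GAM,
                  "adp_c": _GAM, "pi_c": _GAM, "h_c": _GAM},
                 0.0, 1000.0, gpr=genes[BIOMASS_ID], sbo=SBO_BIOMASS)
    model.objective = {BIOMASS_ID: 1.0}

    gene_ids = sorted({g for rule in genes.values() for g in
                       rule.replace(" and ", " ").replace(" or ", " ").split()})
    gene_names = {"P10001": "glcP", "P10002": "oxyT", "P10003": "amtB",
                  "P10004": "pitA", "P10005": "aqpZ", "P10006": "chaA",
                  "P10007": "pyrT", "P10008": "hxk1", "P10009": "glyA1",
                  "P10010": "glyA2", "P10011": "nuoA", "P10012": "atpA",
                  "P10013": "alaC", "P10014": "bofP"}
    for i, gid in enumerate(gene_ids, start=1):
        model.genes.append(Gene(id=gid, name=gene_names.get(gid, gid),
                                annotations=_gene_annotations(gid, i), sbo=SBO_GENE))

    manifest = FixtureManifest(model_id=model.id, seed=seed,
                               ground_truth=_ground_truth(model))
    return model, manifest


# --------------------------------------------------------------------------
# oracle-backed ground truth

def _topological_orphans_dead_ends(model: Model) -> Tuple[List[str], List[str]]:
    producible, consumable = set(), set()
    for rxn in model.reactions:
        if is_boundary(rxn):
            continue
        for mid, coef in rxn.stoichiometry.items():
            forward = rxn.upper_bound > 0
            backward = rxn.lower_bound < 0
            if coef > 0:
                producible.add(mid) if forward else None
                consumable.add(mid) if backward else None
            elif coef < 0:
                consumable.add(mid) if forward else None
                producible.add(mid) if backward else None
    met_ids = [m.id for m in model.metabolites]
    return (sorted(m for m in met_ids if m not in producible),
            sorted(m for m in met_ids if m not in consumable))


def _ground_truth(model: Model) -> dict:
    complete = {r.id: (-1000.0, r.upper_bound) for r in model.reactions if is_boundary(r)}
    fba_default, _ = oracles.fba_oracle(model, {BIOMASS_ID: 1.0})
    fba_complete, _ = oracles.fba_oracle(model, {BIOMASS_ID: 1.0}, complete)
    orphans, dead_ends = _topological_orphans_dead_ends(model)
    return {
        "fba_optimum_default": float(fba_default or 0.0),
        "fba_optimum_complete": float(fba_complete or 0.0),
        "blocked": oracles.fva_blocked_oracle(model),
        "unconserved": oracles.unconserved_per_met_oracle(model),
        "orphans": orphans,
        "dead_ends": dead_ends,
        "essential_genes": sorted(oracles.single_knockout_oracle(model, BIOMASS_ID)),
    }


def make_random_network(seed: int, n_metabolites: int = 5, n_reactions: int = 7) -> Model:
    """Small random stoichiometric network for oracle-equivalence testing.

    Integer coefficients in ±{1, 2}, a random mix of reversibilities and a
    couple of single-metabolite exchange reactions.  No formulas, charges
    or annotations: these fixtures exercise only the LP machinery.
    """
    rng = random.Random(seed)
    model = Model(id=f"random_{seed}", compartments={"c": "cytosol"})
    met_ids = [f"m{i}_c" for i in range(n_metabolites)]
    for mid in met_ids:
        model.metabolites.append(Metabolite(id=mid, name=mid, compartment="c"))
    for j in range(n_reactions):
        size = rng.randint(2, min(3, n_metabolites))
        members = rng.sample(met_ids, size)
        stoich = {}
        # guarantee at least one substrate and one product
        stoich[members[0]] = -rng.choice([1.0, 2.0])
        stoich[members[1]] = rng.choice([1.0, 2.0])
        for mid in members[2:]:
            stoich[mid] = rng.choice([-2.0, -1.0, 1.0, 2.0])
        reversible = rng.random() < 0.4
        model.reactions.append(Reaction(
            id=f"R{j}", name=f"random reaction {j}", stoichiometry=stoich,
            lower_bound=-1000.0 if reversible else 0.0, upper_bound=1000.0))
    for k in range(rng.randint(1, 2)):
        mid = rng.choice(met_ids)
        rid = f"EX_{mid}"
        if any(r.id == rid for r in model.reactions):
            continue
        model.reactions.append(Reaction(
            id=rid, name=f"{mid} exchange", stoichiometry={mid: -1.0},
            lower_bound=-1000.0, upper_bound=1000.0))
    return model


# --------------------------------------------------------------------------
# defect planting

def _annotated_metabolite(mid, name, comp, formula, charge, index, rng) -> Metabolite:
    base = mid[: -(len(comp) + 1)] if mid.endswith("_" + comp) else mid
    return Metabolite(id=mid, name=name, compartment=comp, formula=formula,
                      charge=charge, annotations=_met_annotations(base, index, rng),
                      sbo=SBO_METABOLITE)


def _annotated_reaction(rid, name, stoich, lb, ub, index, gpr="P10008") -> Reaction:
    return Reaction(id=rid, name=name, stoichiometry=dict(stoich),
                    lower_bound=lb, upper_bound=ub, gpr=gpr,
                    annotations=_rxn_annotations(rid, index), sbo=SBO_METABOLIC_REACTION)


def _reactions_involving(model: Model, met_ids: Set[str]) -> List[str]:
    from .biomass import find_biomass_reactions

    biomass = set(find_biomass_reactions(model))
    return sorted(
        r.id for r in model.reactions
        if not is_boundary(r) and r.id not in biomass and met_ids & set(r.stoichiometry)
    )


def plant_defect(model: Model, manifest: FixtureManifest, kind: str,
                 params: Optional[dict] = None, seed: int = 0) -> Tuple[Model, FixtureManifest]:
    """Return a defect-planted copy of the fixture plus its updated manifest.

    ``kind`` must be one of :data:`DEFECT_KINDS`; defects are composable
    (plant repeatedly).  The manifest gains one record naming the planted
    elements, the test ids expected to degrade and the offending ids each
    of those tests should list.
    """
    if kind not in DEFECT_KINDS:
        raise ValueError(f"unknown defect kind {kind!r}")
    params = dict(params or {})
    rng = random.Random(seed + 7919)
    new = model.copy()
    baseline = manifest.ground_truth
    degraded: Set[str] = set()
    offenders: Dict[str, List[str]] = {}
    planted_index = 900 + len(manifest.planted_defects)

    if kind == "unconserved_metabolite":
        # net creation of pyruvate (A -> 2A across the membrane): forces its
        # conservation mass to zero, and is necessarily elementally unbalanced
        rid = "DEFECT_PYR_DOUBLING"
        new.reactions.append(_annotated_reaction(
            rid, "pyruvate doubling (planted)",
            {"pyr_c": -1.0, "pyr_e": 2.0}, 0.0, 1000.0, planted_index))
        degraded |= {"consistency_mass_balance", "consistency_charge_balance"}
        offenders["consistency_mass_balance"] = [rid]
        offenders["consistency_charge_balance"] = [rid]

    elif kind == "unbalanced_reaction":
        rid = params.get("reaction", "HEX1")
        rxn = new.reaction(rid)
        rxn.stoichiometry["h_c"] = rxn.stoichiometry.get("h_c", 0.0) + 1.0
        degraded |= {"consistency_mass_balance", "consistency_charge_balance"}
        offenders["consistency_mass_balance"] = [rid]
        offenders["consistency_charge_balance"] = [rid]

    elif kind == "energy_generating_cycle":
        rid = "DEFECT_ATPGEN"
        new.reactions.append(_annotated_reaction(
            rid, "gratis ATP synthesis (planted)",
            {"adp_c": -1.0, "pi_c": -1.0, "h_c": -1.0, "atp_c": 1.0, "h2o_c": 1.0},
            0.0, 1000.0, planted_index))
        degraded.add("consistency_energy_cycle_atp")
        offenders["consistency_energy_cycle_atp"] = [rid]

    elif kind == "blocked_subnetwork":
        chain = int(params.get("length", 2))
        mets = [f"xblk{i}_c" for i in range(chain + 1)]
        for i, mid in enumerate(mets):
            new.metabolites.append(_annotated_metabolite(
                mid, f"blocked intermediate {i} (planted)", "c",
                "C2H4O2", 0, planted_index + i, rng))
        rids = []
        for i in range(chain):
            rid = f"DEFECT_BLK{i + 1}"
            rids.append(rid)
            new.reactions.append(_annotated_reaction(
                rid, f"blocked step {i + 1} (planted)",
                {mets[i]: -1.0, mets[i + 1]: 1.0}, 0.0, 1000.0, planted_index + i))
        # the chain has no entry and no exit: every step is blocked, its head
        # is an orphan and its tail a dead end (derived below via the oracles)

    elif kind == "orphan_metabolite":
        mid, rid = "orphx_c", "DEFECT_ORPHAN_SINKS"
        new.metabolites.append(_annotated_metabolite(
            mid, "orphan metabolite (planted)", "c", "C3H3O3", -1, planted_index, rng))
        new.reactions.append(_annotated_reaction(
            rid, "consumes the orphan (planted)",
            {mid: -1.0, "pyr_c": 1.0}, 0.0, 1000.0, planted_index))

    elif kind == "dead_end_metabolite":
        mid, rid = "deadx_c", "DEFECT_DEADEND_SOURCE"
        new.metabolites.append(_annotated_metabolite(
            mid, "dead-end metabolite (planted)", "c", "C3H3O3", -1, planted_index, rng))
        new.reactions.append(_annotated_reaction(
            rid, "produces the dead end (planted)",
            {"pyr_c": -1.0, mid: 1.0}, 0.0, 1000.0, planted_index))

    elif kind == "strip_gpr":
        rids = params.get("reactions", ["HEX1", "GLYC", "RESP"])
        for rid in rids:
            new.reaction(rid).gpr = None
        degraded.add("basic_gpr_presence")
        offenders["basic_gpr_presence"] = sorted(rids)

    elif kind == "strip_formula":
        mids = params.get("metabolites", ["nad_c", "nadh_c"])
        for mid in mids:
            new.metabolite(mid).formula = None
        degraded |= {"basic_metabolite_formula_presence", "consistency_mass_balance"}
        offenders["basic_metabolite_formula_presence"] = sorted(mids)
        offenders["consistency_mass_balance"] = _reactions_involving(new, set(mids))

    elif kind == "strip_charge":
        mids = params.get("metabolites", ["nad_c", "nadh_c"])
        for mid in mids:
            new.metabolite(mid).charge = None
        degraded |= {"basic_metabolite_charge_presence", "consistency_charge_balance"}
        offenders["basic_metabolite_charge_presence"] = sorted(mids)
        offenders["consistency_charge_balance"] = _reactions_involving(new, set(mids))

    elif kind == "strip_annotations":
        mids = params.get("metabolites", ["glc_c", "pyr_c"])
        rids = params.get("reactions", ["HEX1", "GLYC"])
        gids = params.get("genes", ["P10008"])
        from .annotations import DEFAULT_REGISTRY

        for mid in mids:
            new.metabolite(mid).annotations = {}
        for rid in rids:
            new.reaction(rid).annotations = {}
        for gene in new.genes:
            if gene.id in gids:
                gene.annotations = {}
        for klass, stripped in (("metabolite", mids), ("reaction", rids), ("gene", gids)):
            if not stripped:
                continue
            degraded.add(f"annotation_{klass}_xref_presence")
            offenders[f"annotation_{klass}_xref_presence"] = sorted(stripped)
            for namespace in DEFAULT_REGISTRY[klass]:
                degraded.add(f"annotation_{klass}_{namespace}")
                offenders[f"annotation_{klass}_{namespace}"] = sorted(stripped)

    elif kind == "strip_sbo":
        mids = params.get("metabolites", ["glc_c", "pyr_c"])
        rids = params.get("reactions", ["HEX1", "GLYC"])
        gids = params.get("genes", ["P10008"])
        for mid in mids:
            new.metabolite(mid).sbo = None
        for rid in rids:
            new.reaction(rid).sbo = None
        for gene in new.genes:
            if gene.id in gids:
                gene.sbo = None
        for label, stripped in (("metabolites", mids), ("reactions", rids), ("genes", gids)):
            if stripped:
                degraded.add(f"annotation_sbo_{label}")
                offenders[f"annotation_sbo_{label}"] = sorted(stripped)

    elif kind == "break_biomass_weight":
        factor = float(params.get("factor", 2.0))
        rxn = new.reaction(BIOMASS_ID)
        rxn.stoichiometry = {m: c * factor for m, c in rxn.stoichiometry.items()}
        degraded.add("biomass_consistency")
        # no offender list: the consistency test reports the weight, not ids

    elif kind == "remove_precursor_path":
        rid = params.get("reaction", "ALATA")
        precursor = params.get("precursor", "ala__L_c")
        new.reactions = [r for r in new.reactions if r.id != rid]
        degraded |= {"biomass_precursors_default", "biomass_precursors_complete"}
        offenders["biomass_precursors_default"] = [precursor]
        offenders["biomass_precursors_complete"] = [precursor]

    # ---- oracle-derived expectations -----------------------------------
    truth = _ground_truth(new)
    eps = 1e-6
    if set(truth["unconserved"]) != set(baseline["unconserved"]):
        degraded.add("consistency_stoichiometric")
        offenders["consistency_stoichiometric"] = sorted(
            set(truth["unconserved"]) - set(baseline["unconserved"]))
    if set(truth["blocked"]) != set(baseline["blocked"]):
        degraded.add("consistency_blocked_reactions")
        offenders["consistency_blocked_reactions"] = truth["blocked"]
    if set(truth["orphans"]) != set(baseline["orphans"]):
        degraded.add("consistency_orphan_metabolites")
        offenders["consistency_orphan_metabolites"] = truth["orphans"]
    if set(truth["dead_ends"]) != set(baseline["dead_ends"]):
        degraded.add("consistency_dead_end_metabolites")
        offenders["consistency_dead_end_metabolites"] = truth["dead_ends"]
    if baseline["fba_optimum_default"] > eps >= truth["fba_optimum_default"]:
        degraded.add("biomass_growth_default")
    if baseline["fba_optimum_complete"] > eps >= truth["fba_optimum_complete"]:
        degraded.add("biomass_growth_complete")

    record = {
        "kind": kind,
        "params": params,
        "degraded_tests": sorted(degraded),
        "offenders": {tid: sorted(ids) for tid, ids in offenders.items()},
    }
    new_manifest = FixtureManifest(
        model_id=new.id,
        seed=manifest.seed,
        planted_defects=manifest.planted_defects + [record],
        ground_truth=truth,
    )
    return new, new_manifest
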