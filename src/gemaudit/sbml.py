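"""Reading SBML models and validating document structure.

Parsing into the package's :class:`~gemaudit.model.Model` is delegated to
cobrapy's SBML reader (SBML L3 + fbc primary; legacy L2 documents with
kinetic-law bound parameters are accepted as well).  Structural validation
is performed directly on the document with libsbml, analogous to the SBML
validator: problems are *returned* as issues, never raised.
"""

from __future__ import annotations

import logging
import os
import warnings
from typing import Dict, List

import cobra
import libsbml

from .model import Gene, Metabolite, Model, Reaction, StructuralError, StructuralIssue

__all__ = ["read_sbml", "write_sbml", "validate_structure", "to_cobra", "from_cobra"]

logger = logging.getLogger(__name__)


def _norm_annotations(annotation) -> Dict[str, List[str]]:
    """Normalize a cobra annotation mapping to namespace -> list of ids."""
    out: Dict[str, List[str]] = {}
    for namespace, values in annotation.items():
        if namespace == "sbo":
            continue
        if isinstance(values, str):
            out[namespace] = [values]
        else:
            out[namespace] = [str(v) for v in values]
    return out


def _sbo_of(annotation) -> str | None:
    sbo = annotation.get("sbo")
    if isinstance(sbo, (list, tuple)):
        sbo = sbo[0] if sbo else None
    return sbo


def from_cobra(cm: "cobra.Model") -> Model:
    """Convert a cobrapy model into the package's container."""
    model = Model(id=cm.id or "model")
    model.compartments = {k: v or k for k, v in cm.compartments.items()}
    for met in cm.metabolites:
        model.metabolites.append(
            Metabolite(
                id=met.id,
                name=met.name or "",
                compartment=met.compartment or "",
                formula=met.formula if met.formula else None,
                charge=int(met.charge) if met.charge is not None else None,
                annotations=_norm_annotations(met.annotation),
                sbo=_sbo_of(met.annotation),
            )
        )
    for rxn in cm.reactions:
        model.reactions.append(
            Reaction(
                id=rxn.id,
                name=rxn.name or "",
                stoichiometry={m.id: float(c) for m, c in rxn.metabolites.items()},
                lower_bound=float(rxn.lower_bound),
                upper_bound=float(rxn.upper_bound),
                gpr=rxn.gene_reaction_rule or None,
                annotations=_norm_annotations(rxn.annotation),
                sbo=_sbo_of(rxn.annotation),
            )
        )
    for gene in cm.genes:
        model.genes.append(
            Gene(
                id=gene.id,
                name=gene.name or "",
                annotations=_norm_annotations(gene.annotation),
                sbo=_sbo_of(gene.annotation),
            )
        )
    from cobra.util.solver import linear_reaction_coefficients

    model.objective = {r.id: float(c) for r, c in linear_reaction_coefficients(cm).items()}
    return model


def to_cobra(model: Model) -> "cobra.Model":
    """Convert to a cobrapy model (used for FBA/FVA and SBML writing)."""
    cm = cobra.Model(model.id)
    mets = {}
    for met in model.metabolites:
        cmet = cobra.Metabolite(
            met.id,
            formula=met.formula,
            name=met.name,
            charge=met.charge,
            compartment=met.compartment or None,
        )
        for namespace, values in met.annotations.items():
            cmet.annotation[namespace] = list(values)
        if met.sbo:
            cmet.annotation["sbo"] = met.sbo
        mets[met.id] = cmet
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for rxn in model.reactions:
        crxn = cobra.Reaction(rxn.id, name=rxn.name,
                              lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound)
        rxns.append(crxn)
    cm.add_reactions(rxns)
    for rxn in model.reactions:
        crxn = cm.reactions.get_by_id(rxn.id)
        crxn.add_metabolites({mets[m]: c for m, c in rxn.stoichiometry.items()})
        if rxn.gpr:
            crxn.gene_reaction_rule = rxn.gpr
        for namespace, values in rxn.annotations.items():
            crxn.annotation[namespace] = list(values)
        if rxn.sbo:
            crxn.annotation["sbo"] = rxn.sbo
    for gene in model.genes:
        if gene.id not in cm.genes:
            cm.genes.append(cobra.Gene(gene.id))
        cgene = cm.genes.get_by_id(gene.id)
        cgene.name = gene.name
        for namespace, values in gene.annotations.items():
            cgene.annotation[namespace] = list(values)
        if gene.sbo:
            cgene.annotation["sbo"] = gene.sbo
    if model.compartments:
        cm.compartments = dict(model.compartments)
    if model.objective:
        from cobra.util.solver import set_objective

        set_objective(cm, {cm.reactions.get_by_id(r): w for r, w in model.objective.items()})
    return cm


def read_sbml(path: str) -> Model:
    """Read an SBML (L3+fbc or legacy) file into a :class:`Model`.

    Raises :class:`StructuralError` if the document cannot be parsed;
    missing bounds are defaulted to ±1000 by the reader with a warning.
    """
    if not os.path.exists(path):
        raise StructuralError(f"no such file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = cobra.io.read_sbml_model(path)
    except Exception as exc:  # noqa: BLE001 - reader errors become structural
        raise StructuralError(f"cannot parse SBML document {path}: {exc}") from exc
    return from_cobra(cm)


def write_sbml(model: Model, path: str) -> None:
    """Serialize to SBML L3 + fbc (used by the fixture generator)."""
    cobra.io.write_sbml_model(to_cobra(model), path)


def _issue(severity: str, code: str, message: str, element_id=None) -> StructuralIssue:
    return StructuralIssue(severity=severity, code=code, message=message, element_id=element_id)


def validate_structure(path: str) -> List[StructuralIssue]:
    """Validate an SBML document; returns all issues, empty list iff clean."""
    issues: List[StructuralIssue] = []
    if not os.path.exists(path):
        return [_issue("error", "file-missing", f"no such file: {path}")]
    doc = libsbml.readSBMLFromFile(path)
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            issues.append(
                _issue("error", f"sbml-{err.getErrorId()}",
                       f"line {err.getLine()}: {err.getMessage().strip()}")
            )
    sbml_model = doc.getModel()
    if sbml_model is None:
        if not issues:
            issues.append(_issue("error", "no-model", "document contains no <model> element"))
        return issues
    seen = set()
    # duplicate identifiers among species / reactions / fbc gene products
    for kind, elements in (
        ("species", [sbml_model.getSpecies(i) for i in range(sbml_model.getNumSpecies())]),
        ("reaction", [sbml_model.getReaction(i) for i in range(sbml_model.getNumReactions())]),
    ):
        counted: Dict[str, int] = {}
        for element in elements:
            counted[element.getId()] = counted.get(element.getId(), 0) + 1
        for element_id, n in counted.items():
            if n > 1:
                issues.append(
                    _issue("error", f"duplicate-{kind}-id",
                           f"{kind} id {element_id!r} declared {n} times", element_id)
                )
                seen.add(element_id)
    # dangling references from reactions to species
    declared = {sbml_model.getSpecies(i).getId() for i in range(sbml_model.getNumSpecies())}
    declared_comps = {
        sbml_model.getCompartment(i).getId() for i in range(sbml_model.getNumCompartments())
    }
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        refs = [rxn.getReactant(j) for j in range(rxn.getNumReactants())]
        refs += [rxn.getProduct(j) for j in range(rxn.getNumProducts())]
        for ref in refs:
            if ref.getSpecies() not in declared:
                issues.append(
                    _issue("error", "dangling-species-reference",
                           f"reaction {rxn.getId()!r} references undeclared species "
                           f"{ref.getSpecies()!r}", rxn.getId())
                )
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.isSetCompartment() and sp.getCompartment() not in declared_comps:
            issues.append(
                _issue("error", "undeclared-compartment",
                       f"species {sp.getId()!r} placed in undeclared compartment "
                       f"{sp.getCompartment()!r}", sp.getId())
            )
    # fbc completeness (L3 only): reactions should declare flux bounds
    fbc = sbml_model.getPlugin("fbc")
    if doc.getLevel() >= 3 and fbc is not None:
        for i in range(sbml_model.getNumReactions()):
            rxn = sbml_model.getReaction(i)
            rplug = rxn.getPlugin("fbc")
            if rplug is None or not rplug.isSetLowerFluxBound() or not rplug.isSetUpperFluxBound():
                issues.append(
                    _issue("warning", "missing-flux-bounds",
                           f"reaction {rxn.getId()!r} lacks fbc flux bounds "
                           "(defaulted to ±1000 on load)", rxn.getId())
                )
    return issues
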