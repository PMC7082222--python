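"""Annotation battery: MIRIAM cross-references, namespaces, SBO coverage.

Identifier patterns are a vendored subset of the identifiers.org registry
so that audits run offline; every pattern is applied with full-match
semantics.  The registry is overridable through the configuration file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .config import Config
from .model import (
    Model,
    SBO_BIOMASS,
    SBO_DEMAND,
    SBO_EXCHANGE,
    SBO_GENE,
    SBO_METABOLIC_REACTION,
    SBO_METABOLITE,
    SBO_SINK,
    boundary_kind,
    strip_compartment_suffix,
)
from .results import TestResult

__all__ = [
    "DEFAULT_REGISTRY",
    "build_registry",
    "AnnotationAudit",
    "audit_cross_references",
    "primary_namespace_consistency",
    "sbo_coverage",
]

DEFAULT_REGISTRY: Dict[str, Dict[str, str]] = {
    "metabolite": {
        "kegg.compound": r"C\d+",
        "chebi": r"CHEBI:\d+",
        "metanetx.chemical": r"MNXM\d+",
        "bigg.metabolite": r"[a-z_A-Z0-9]+",
        "seed.compound": r"cpd\d+",
        "inchikey": r"[A-Z]{14}-[A-Z]{10}-[A-Z]",
        "hmdb": r"HMDB\d+",
        "pubchem.compound": r"\d+",
    },
    "reaction": {
        "rhea": r"\d{5}",
        "kegg.reaction": r"R\d+",
        "metanetx.reaction": r"MNXR\d+",
        "bigg.reaction": r"[a-z_A-Z0-9]+",
        "ec-code": r"\d+(\.(\d+|-)){1,3}",
        "seed.reaction": r"rxn\d+",
        "biocyc": r"[A-Z0-9][A-Za-z0-9+_.%\-]*(:[A-Za-z0-9+_.%\-]+)?",
    },
    "gene": {
        "refseq": r"[A-Z]{2}_\d+(\.\d+)?",
        "uniprot": r"([A-NR-Z][0-9][A-Z][A-Z0-9]{2}[0-9]|[OPQ][0-9][A-Z0-9]{3}[0-9])(\.\d+)?",
        "ncbigene": r"\d+",
        "kegg.genes": r"\w+:[\w\d.\-]*",
    },
}


def build_registry(config: Optional[Config] = None) -> Dict[str, Dict[str, re.Pattern]]:
    """Compile the default registry with any configured overrides applied."""
    merged = {klass: dict(namespaces) for klass, namespaces in DEFAULT_REGISTRY.items()}
    if config is not None:
        for klass, namespaces in config.registry_overrides.items():
            merged.setdefault(klass, {}).update(namespaces)
    return {
        klass: {ns: re.compile(pattern) for ns, pattern in namespaces.items()}
        for klass, namespaces in merged.items()
    }


@dataclass
class NamespaceAudit:
    missing: List[str] = field(default_factory=list)
    invalid: List[str] = field(default_factory=list)


@dataclass
class AnnotationAudit:
    component_class: str
    total: int
    missing_any: List[str] = field(default_factory=list)
    namespaces: Dict[str, NamespaceAudit] = field(default_factory=dict)


def _elements(model: Model, component_class: str):
    return {
        "metabolite": model.metabolites,
        "reaction": model.reactions,
        "gene": model.genes,
    }[component_class]


def audit_cross_references(model: Model, registry=None,
                           config: Optional[Config] = None) -> Dict[str, AnnotationAudit]:
    """Per class and namespace: which elements lack or fail each cross-reference."""
    registry = registry or build_registry(config)
    audits: Dict[str, AnnotationAudit] = {}
    for klass, namespaces in registry.items():
        elements = _elements(model, klass)
        audit = AnnotationAudit(component_class=klass, total=len(elements))
        for element in elements:
            if not any(values for values in element.annotations.values()):
                audit.missing_any.append(element.id)
        audit.missing_any.sort()
        for namespace, pattern in namespaces.items():
            ns_audit = NamespaceAudit()
            for element in elements:
                values = element.annotations.get(namespace, [])
                if not values:
                    ns_audit.missing.append(element.id)
                elif not all(pattern.fullmatch(v) for v in values):
                    ns_audit.invalid.append(element.id)
            ns_audit.missing.sort()
            ns_audit.invalid.sort()
            audit.namespaces[namespace] = ns_audit
        audits[klass] = audit
    return audits


def primary_namespace_consistency(
    model: Model, registry=None, config: Optional[Config] = None
) -> Dict[str, Tuple[Optional[str], float]]:
    """Best-matching namespace for native ids per class and its coverage.

    Metabolite ids are stripped of their compartment suffix before
    matching.  Classes with no elements are omitted.
    """
    registry = registry or build_registry(config)
    out: Dict[str, Tuple[Optional[str], float]] = {}
    for klass, namespaces in registry.items():
        elements = _elements(model, klass)
        if not elements:
            continue
        ids = [e.id for e in elements]
        if klass == "metabolite":
            ids = [strip_compartment_suffix(i, model.compartments) for i in ids]
        best_ns, best_fraction = None, 0.0
        for namespace in sorted(namespaces):
            pattern = namespaces[namespace]
            fraction = sum(1 for i in ids if pattern.fullmatch(i)) / len(ids)
            if fraction > best_fraction:
                best_ns, best_fraction = namespace, fraction
        out[klass] = (best_ns, best_fraction)
    return out


def _expected_reaction_sbo(model: Model, rxn) -> str:
    kind = boundary_kind(rxn)
    if kind == "exchange":
        return SBO_EXCHANGE
    if kind == "demand":
        return SBO_DEMAND
    if kind == "sink":
        return SBO_SINK
    if "biomass" in rxn.id.lower() or "biomass" in rxn.name.lower() or rxn.sbo == SBO_BIOMASS:
        return SBO_BIOMASS
    return SBO_METABOLIC_REACTION


def sbo_coverage(model: Model, config: Optional[Config] = None) -> List[TestResult]:
    """Fraction of components carrying the SBO term expected for their role.

    Expected terms: metabolite 247, gene 243, metabolic reaction 176,
    exchange 627, demand 628, sink 632, biomass 629.  SBO tests carry
    double weight in the annotation section.
    """
    results = []
    specs = [
        ("metabolites", model.metabolites, lambda e: SBO_METABOLITE),
        ("reactions", model.reactions, lambda e: _expected_reaction_sbo(model, e)),
        ("genes", model.genes, lambda e: SBO_GENE),
    ]
    for label, elements, expected_for in specs:
        if not elements:
            results.append(TestResult(
                test_id=f"annotation_sbo_{label}", section="annotation", metric=None,
                message=f"no {label}; SBO coverage undefined", weight=2.0))
            continue
        wrong = sorted(e.id for e in elements if e.sbo != expected_for(e))
        results.append(TestResult(
            test_id=f"annotation_sbo_{label}",
            section="annotation",
            metric=1.0 - len(wrong) / len(elements),
            data=wrong,
            message=f"{len(wrong)} of {len(elements)} {label} lack the expected SBO term",
            weight=2.0,
        ))
    return results
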