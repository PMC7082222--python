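"""Deterministic sorted-YAML serialization of a model.

A model is rendered to YAML with every list sorted lexicographically by id
and every mapping key-sorted, so that two semantically identical models —
regardless of element insertion order — produce byte-identical files.
This makes version-control diffs of model edits line-by-line readable and
provides a stable content digest for history reports.
"""

from __future__ import annotations

import hashlib

import yaml

from .model import Model

__all__ = ["sorted_yaml", "write_sorted_yaml", "model_digest"]


def _float(value: float):
    """Fixed float rendering: integral floats as ints, else repr with 10 sig digits."""
    if value == int(value):
        return int(value)
    return float(f"{value:.10g}")


def _met_entry(met):
    entry = {"id": met.id, "name": met.name, "compartment": met.compartment}
    if met.formula is not None:
        entry["formula"] = met.formula
    if met.charge is not None:
        entry["charge"] = int(met.charge)
    if met.annotations:
        entry["annotations"] = {k: sorted(v) for k, v in sorted(met.annotations.items())}
    if met.sbo:
        entry["sbo"] = met.sbo
    return entry


def _rxn_entry(rxn):
    entry = {
        "id": rxn.id,
        "name": rxn.name,
        "stoichiometry": {m: _float(c) for m, c in sorted(rxn.stoichiometry.items())},
        "lower_bound": _float(rxn.lower_bound),
        "upper_bound": _float(rxn.upper_bound),
    }
    if rxn.gpr:
        entry["gpr"] = rxn.gpr
    if rxn.annotations:
        entry["annotations"] = {k: sorted(v) for k, v in sorted(rxn.annotations.items())}
    if rxn.sbo:
        entry["sbo"] = rxn.sbo
    return entry


def _gene_entry(gene):
    entry = {"id": gene.id, "name": gene.name}
    if gene.annotations:
        entry["annotations"] = {k: sorted(v) for k, v in sorted(gene.annotations.items())}
    if gene.sbo:
        entry["sbo"] = gene.sbo
    return entry


def sorted_yaml(model: Model) -> str:
    """Render the model to the canonical sorted YAML text."""
    document = {
        "model": {"id": model.id},
        "compartments": dict(sorted(model.compartments.items())),
        "metabolites": [_met_entry(m) for m in sorted(model.metabolites, key=lambda m: m.id)],
        "reactions": [_rxn_entry(r) for r in sorted(model.reactions, key=lambda r: r.id)],
        "genes": [_gene_entry(g) for g in sorted(model.genes, key=lambda g: g.id)],
        "objective": {k: _float(v) for k, v in sorted(model.objective.items())},
    }
    return yaml.safe_dump(document, sort_keys=False, default_flow_style=False, width=100)


def write_sorted_yaml(model: Model, path: str) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(sorted_yaml(model))


def model_digest(model: Model) -> str:
    """SHA-256 of the sorted-YAML serialization — a stable content hash."""
    return hashlib.sha256(sorted_yaml(model).encode("utf-8")).hexdigest()
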