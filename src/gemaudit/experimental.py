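"""Experimental validation: growth media and gene-essentiality comparisons.

A YAML manifest names tabular data files (csv/tsv/xls/xlsx)::

    version: 1
    media:
      glucose: {filename: media/glucose.csv}
    growth:
      - {filename: growth.csv}
    essentiality:
      - {filename: essentiality.csv, medium: glucose}   # medium optional

Media tables have columns ``exchange, lower, upper``; growth tables
``medium, growth``; essentiality tables ``gene, essential``.  Boolean
flags accept TRUE/FALSE, 1/0 and yes/no case-insensitively.  Media are
applied on a closed-uptake baseline (all exchange lower bounds zeroed
first) so that a medium definition is self-contained.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from . import gpr as gpr_mod
from .biomass import find_biomass_reactions
from .config import Config
from .model import Model, is_boundary
from .sbml import to_cobra

__all__ = [
    "Medium",
    "GrowthObservation",
    "EssentialityObservation",
    "ExperimentRecord",
    "ValidationOutcome",
    "ConfigError",
    "load_experiment_config",
    "evaluate_growth",
    "evaluate_essentiality",
]


class ConfigError(ValueError):
    """Manifest or data table malformed (missing file, bad header, bad flag)."""


@dataclass
class Medium:
    name: str
    exchange_bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)


@dataclass
class GrowthObservation:
    medium: str
    observed_growth: bool


@dataclass
class EssentialityObservation:
    gene: str
    observed_essential: bool
    medium: Optional[str] = None


@dataclass
class ExperimentRecord:
    experiment: str
    predicted: Optional[bool]
    observed: bool
    agreement: Optional[bool]
    note: str = ""


@dataclass
class ValidationOutcome:
    records: List[ExperimentRecord]

    @property
    def confusion(self) -> Dict[str, int]:
        counts = {"tp": 0, "tn": 0, "fp": 0, "fn": 0, "unevaluable": 0}
        for record in self.records:
            if record.predicted is None:
                counts["unevaluable"] += 1
            elif record.predicted and record.observed:
                counts["tp"] += 1
            elif record.predicted and not record.observed:
                counts["fp"] += 1
            elif not record.predicted and record.observed:
                counts["fn"] += 1
            else:
                counts["tn"] += 1
        return counts

    @property
    def accuracy(self) -> Optional[float]:
        c = self.confusion
        total = c["tp"] + c["tn"] + c["fp"] + c["fn"]
        if total == 0:
            return None
        return (c["tp"] + c["tn"]) / total

    @property
    def matthews(self) -> Optional[float]:
        c = self.confusion
        total = c["tp"] + c["tn"] + c["fp"] + c["fn"]
        if total == 0:
            return None
        denom = math.sqrt(
            (c["tp"] + c["fp"]) * (c["tp"] + c["fn"]) * (c["tn"] + c["fp"]) * (c["tn"] + c["fn"])
        )
        if denom == 0:
            return 0.0
        return (c["tp"] * c["tn"] - c["fp"] * c["fn"]) / denom


_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _parse_flag(value, context: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ConfigError(f"unparseable boolean flag {value!r} in {context}")


def _read_table(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise ConfigError(f"data file not found: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext == ".csv":
        frame = pd.read_csv(path)
    elif ext == ".tsv":
        frame = pd.read_csv(path, sep="\t")
    elif ext in (".xls", ".xlsx"):
        frame = pd.read_excel(path)
    else:
        raise ConfigError(f"unsupported data format {ext!r} for {path}")
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    return frame


def _require_columns(frame: pd.DataFrame, required: List[str], path: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ConfigError(
            f"{path}: missing required column(s) {missing}; found {list(frame.columns)}"
        )


def load_experiment_config(path: str):
    """Load a manifest and its tables into typed records.

    Returns ``(media, growth_observations, essentiality_observations)``.
    Unknown model identifiers are *not* resolved here; evaluation marks
    them unevaluable instead of failing the load.
    """
    import yaml

    if not os.path.exists(path):
        raise ConfigError(f"manifest not found: {path}")
    with open(path, "r", encoding="utf-8") as handle:
        manifest = yaml.safe_load(handle) or {}
    base = os.path.dirname(os.path.abspath(path))

    def resolve(filename: str) -> str:
        return filename if os.path.isabs(filename) else os.path.join(base, filename)

    media: Dict[str, Medium] = {}
    for name, entry in (manifest.get("media") or {}).items():
        frame = _read_table(resolve(entry["filename"]))
        _require_columns(frame, ["exchange", "lower", "upper"], entry["filename"])
        bounds = {
            str(row.exchange): (float(row.lower), float(row.upper))
            for row in frame.itertuples()
        }
        media[name] = Medium(name=name, exchange_bounds=bounds)

    growth: List[GrowthObservation] = []
    for entry in manifest.get("growth") or []:
        frame = _read_table(resolve(entry["filename"]))
        _require_columns(frame, ["medium", "growth"], entry["filename"])
        for row in frame.itertuples():
            growth.append(GrowthObservation(
                medium=str(row.medium),
                observed_growth=_parse_flag(row.growth, entry["filename"]),
            ))

    essentiality: List[EssentialityObservation] = []
    for entry in manifest.get("essentiality") or []:
        frame = _read_table(resolve(entry["filename"]))
        _require_columns(frame, ["gene", "essential"], entry["filename"])
        for row in frame.itertuples():
            essentiality.append(EssentialityObservation(
                gene=str(row.gene),
                observed_essential=_parse_flag(row.essential, entry["filename"]),
                medium=entry.get("medium"),
            ))
    return media, growth, essentiality


def _biomass_id(model: Model) -> str:
    candidates = find_biomass_reactions(model)
    if not candidates:
        raise ValueError("no biomass reaction found for experimental evaluation")
    return candidates[0]


def evaluate_growth(model: Model, media: Dict[str, Medium],
                    observations: List[GrowthObservation],
                    config: Optional[Config] = None) -> ValidationOutcome:
    """Predict growth/no-growth per medium by FBA and tally agreement."""
    config = config or Config()
    biomass = _biomass_id(model)
    cm = to_cobra(model)
    exchange_ids = {r.id for r in model.reactions if is_boundary(r)}
    records = []
    for obs in observations:
        medium = media.get(obs.medium)
        if medium is None:
            records.append(ExperimentRecord(obs.medium, None, obs.observed_growth, None,
                                            note="unknown medium"))
            continue
        unknown = [rid for rid in medium.exchange_bounds if rid not in exchange_ids]
        if unknown:
            records.append(ExperimentRecord(obs.medium, None, obs.observed_growth, None,
                                            note=f"unknown exchange(s): {sorted(unknown)}"))
            continue
        with cm:
            for rid in exchange_ids:  # closed-uptake baseline
                cm.reactions.get_by_id(rid).lower_bound = 0.0
            for rid, (lb, ub) in medium.exchange_bounds.items():
                cm.reactions.get_by_id(rid).bounds = (lb, ub)
            cm.objective = cm.reactions.get_by_id(biomass)
            solution = cm.optimize()
            value = solution.objective_value if solution.status == "optimal" else 0.0
        predicted = bool(value is not None and value > config.eps_growth)
        records.append(ExperimentRecord(obs.medium, predicted, obs.observed_growth,
                                        predicted == obs.observed_growth))
    return ValidationOutcome(records=records)


def evaluate_essentiality(model: Model, observations: List[EssentialityObservation],
                          media: Optional[Dict[str, Medium]] = None,
                          config: Optional[Config] = None) -> ValidationOutcome:
    """Predict gene essentiality by GPR-aware single knockouts and compare.

    A knockout disables every reaction whose GPR evaluates false without
    the gene; the gene is predicted essential iff the biomass optimum
    falls below ``eps_growth``.
    """
    config = config or Config()
    media = media or {}
    biomass = _biomass_id(model)
    cm = to_cobra(model)
    exchange_ids = {r.id for r in model.reactions if is_boundary(r)}
    known_genes = {g.id for g in model.genes}
    trees = {}
    for rxn in model.reactions:
        if rxn.gpr:
            trees[rxn.id] = gpr_mod.parse_gpr(rxn.gpr)
    records = []
    for obs in observations:
        if obs.gene not in known_genes:
            records.append(ExperimentRecord(obs.gene, None, obs.observed_essential, None,
                                            note="unknown gene"))
            continue
        disabled = [rid for rid, tree in trees.items()
                    if not gpr_mod.eval_gpr(tree, {obs.gene})]
        with cm:
            if obs.medium is not None:
                medium = media.get(obs.medium)
                if medium is None:
                    records.append(ExperimentRecord(obs.gene, None, obs.observed_essential,
                                                    None, note="unknown medium"))
                    continue
                for rid in exchange_ids:
                    cm.reactions.get_by_id(rid).lower_bound = 0.0
                for rid, (lb, ub) in medium.exchange_bounds.items():
                    cm.reactions.get_by_id(rid).bounds = (lb, ub)
            for rid in disabled:
                cm.reactions.get_by_id(rid).bounds = (0.0, 0.0)
            cm.objective = cm.reactions.get_by_id(biomass)
            solution = cm.optimize()
            value = solution.objective_value if solution.status == "optimal" else 0.0
        predicted = bool(value is None or value < config.eps_growth)
        records.append(ExperimentRecord(obs.gene, predicted, obs.observed_essential,
                                        predicted == obs.observed_essential))
    return ValidationOutcome(records=records)
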