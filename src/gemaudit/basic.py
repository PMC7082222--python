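"""Basic tests: formal correctness and presence of model components."""

from __future__ import annotations

from typing import List, Optional

from . import formula as formula_mod
from .model import Model, is_boundary
from .results import TestResult

__all__ = [
    "test_components_present",
    "test_formula_and_charge",
    "test_gpr_presence",
    "metabolic_coverage",
]


def test_components_present(model: Model) -> List[TestResult]:
    """One presence check per component class (metric 1 iff count > 0)."""
    results = []
    for name, count in (
        ("metabolites", len(model.metabolites)),
        ("reactions", len(model.reactions)),
        ("compartments", len(model.compartments)),
        ("genes", len(model.genes)),
    ):
        results.append(
            TestResult(
                test_id=f"basic_{name}_present",
                section="basic",
                metric=1.0 if count > 0 else 0.0,
                data=[count],
                message=f"model declares {count} {name}",
            )
        )
    return results


def test_formula_and_charge(model: Model) -> List[TestResult]:
    """Fraction of metabolites carrying a parseable formula / a charge.

    A wildcard formula (e.g. containing R groups) counts as *present*: the
    information exists even though no molecular weight can be derived.
    Wildcard carriers are listed in the result data under a separate tag.
    """
    total = len(model.metabolites)
    missing_formula, wildcard, missing_charge = [], [], []
    for met in model.metabolites:
        if met.formula is None or met.formula.strip() == "":
            missing_formula.append(met.id)
        else:
            try:
                parsed = formula_mod.parse_formula(met.formula)
                if not parsed.is_fully_specified:
                    wildcard.append(met.id)
            except formula_mod.FormulaError:
                missing_formula.append(met.id)
    for met in model.metabolites:
        if met.charge is None:
            missing_charge.append(met.id)
    if total == 0:
        unscored = dict(metric=None, message="model has no metabolites")
        return [
            TestResult(test_id="basic_metabolite_formula_presence", section="basic", **unscored),
            TestResult(test_id="basic_metabolite_charge_presence", section="basic", **unscored),
        ]
    return [
        TestResult(
            test_id="basic_metabolite_formula_presence",
            section="basic",
            metric=1.0 - len(missing_formula) / total,
            data=sorted(missing_formula) + [{"wildcard": sorted(wildcard)}] if wildcard
            else sorted(missing_formula),
            message=f"{len(missing_formula)} of {total} metabolites lack a parseable formula",
        ),
        TestResult(
            test_id="basic_metabolite_charge_presence",
            section="basic",
            metric=1.0 - len(missing_charge) / total,
            data=sorted(missing_charge),
            message=f"{len(missing_charge)} of {total} metabolites lack a charge",
        ),
    ]


def test_gpr_presence(model: Model) -> TestResult:
    """Fraction of non-boundary reactions carrying a GPR rule.

    Boundary pseudo-reactions have no enzymes and are excluded from the
    denominator.  An empty denominator (e.g. an exchange-only model)
    leaves the test unscored.
    """
    internal = [r for r in model.reactions if not is_boundary(r)]
    if not internal:
        return TestResult(
            test_id="basic_gpr_presence", section="basic", metric=None,
            message="no non-boundary reactions; GPR coverage undefined",
        )
    missing = sorted(r.id for r in internal if not r.gpr or not r.gpr.strip())
    return TestResult(
        test_id="basic_gpr_presence",
        section="basic",
        metric=1.0 - len(missing) / len(internal),
        data=missing,
        message=f"{len(missing)} of {len(internal)} non-boundary reactions lack GPR rules",
    )


def metabolic_coverage(model: Model) -> TestResult:
    """Informational ratio #reactions / #genes (degree of metabolic coverage)."""
    if not model.genes:
        return TestResult(
            test_id="basic_metabolic_coverage", section="basic", metric=None,
            message="no genes; metabolic coverage undefined",
        )
    ratio = len(model.reactions) / len(model.genes)
    return TestResult(
        test_id="basic_metabolic_coverage", section="basic", metric=None,
        data=[ratio], message=f"metabolic coverage (reactions/genes) = {ratio:.3f}",
        scored=False,
    )


def coverage_ratio(model: Model) -> Optional[float]:
    """Plain numeric accessor for the coverage ratio (None when undefined)."""
    if not model.genes:
        return None
    return len(model.reactions) / len(model.genes)
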