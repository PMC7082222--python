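"""The full QC battery: run every applicable test and collect a ResultSet.

Individual test failures are captured as errored, unscored results — the
suite itself never aborts on a loadable model.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

from . import annotations as annotations_mod
from . import basic as basic_mod
from . import biomass as biomass_mod
from . import consistency as consistency_mod
from . import experimental as experimental_mod
from .config import Config
from .model import Model
from .results import ResultSet, TestResult
from .sbml import to_cobra
from .yamlio import model_digest

__all__ = ["run_suite"]

TOOL_VERSION = "0.1.0"


def _guard(results: List[TestResult], section: str, test_id: str, producer) -> None:
    """Append the producer's result(s); convert an exception into an errored result."""
    try:
        produced = producer()
    except Exception as exc:  # noqa: BLE001 - capture, never abort the suite
        results.append(TestResult(test_id=test_id, section=section, metric=None,
                                  message=f"test errored: {exc}"))
        return
    if isinstance(produced, TestResult):
        results.append(produced)
    else:
        results.extend(produced)


def _consistency_results(model: Model, config: Config, cm) -> List[TestResult]:
    results: List[TestResult] = []
    n_mets = len(model.metabolites)
    n_rxns = len(model.reactions)

    def stoichiometric():
        cert = consistency_mod.find_unconserved_metabolites(model, config)
        if n_mets == 0:
            return TestResult(test_id="consistency_stoichiometric", section="consistency",
                              metric=None, message="no metabolites", weight=3.0)
        return TestResult(
            test_id="consistency_stoichiometric", section="consistency",
            metric=1.0 - len(cert.unconserved) / n_mets,
            data=cert.unconserved, weight=3.0,
            message=f"{len(cert.unconserved)} of {n_mets} metabolites unconserved",
        )

    _guard(results, "consistency", "consistency_stoichiometric", stoichiometric)

    def balance():
        report = consistency_mod.check_mass_charge_balance(model)
        internal = list(report.reactions.values())
        out = []
        for label, attr in (("mass", "mass_status"), ("charge", "charge_status")):
            if not internal:
                out.append(TestResult(
                    test_id=f"consistency_{label}_balance", section="consistency",
                    metric=None, message="no internal reactions"))
                continue
            bad = sorted(b.reaction_id for b in internal if getattr(b, attr) != "balanced")
            undetermined = sorted(
                b.reaction_id for b in internal if getattr(b, attr) == "undetermined")
            out.append(TestResult(
                test_id=f"consistency_{label}_balance", section="consistency",
                metric=1.0 - len(bad) / len(internal),
                data=bad,
                message=(f"{len(bad)} of {len(internal)} internal reactions not "
                         f"{label}-balanced ({len(undetermined)} undetermined)"),
            ))
        return out

    _guard(results, "consistency", "consistency_mass_balance", balance)

    def blocked():
        blocked_ids = consistency_mod.find_blocked_reactions(model, config, cobra_model=cm)
        if n_rxns == 0:
            return TestResult(test_id="consistency_blocked_reactions", section="consistency",
                              metric=None, message="no reactions")
        return TestResult(
            test_id="consistency_blocked_reactions", section="consistency",
            metric=1.0 - len(blocked_ids) / n_rxns, data=blocked_ids,
            message=f"{len(blocked_ids)} of {n_rxns} reactions permanently blocked",
        )

    _guard(results, "consistency", "consistency_blocked_reactions", blocked)

    def orphans_dead_ends():
        orphans, dead_ends = consistency_mod.find_orphans_and_dead_ends(model)
        out = []
        for label, ids in (("orphan", orphans), ("dead_end", dead_ends)):
            if n_mets == 0:
                out.append(TestResult(
                    test_id=f"consistency_{label}_metabolites", section="consistency",
                    metric=None, message="no metabolites"))
            else:
                out.append(TestResult(
                    test_id=f"consistency_{label}_metabolites", section="consistency",
                    metric=1.0 - len(ids) / n_mets, data=ids,
                    message=f"{len(ids)} of {n_mets} metabolites are {label.replace('_', ' ')}s",
                ))
        return out

    _guard(results, "consistency", "consistency_orphan_metabolites", orphans_dead_ends)

    for key in sorted(config.energy_couples):
        def energy(key=key):
            cycle = consistency_mod.detect_energy_generating_cycle(
                model, key, config, cobra_model=cm)
            if cycle.dissipation_flux is None:
                return TestResult(
                    test_id=f"consistency_energy_cycle_{key}", section="consistency",
                    metric=None,
                    message=f"energy couple for {key!r} not present in the model")
            has = cycle.has_cycle(config.eps_flux)
            return TestResult(
                test_id=f"consistency_energy_cycle_{key}", section="consistency",
                metric=0.0 if has else 1.0, data=cycle.cycle_reactions,
                message=(f"{key} dissipation flux {cycle.dissipation_flux:.6g} "
                         f"mmol·gDW⁻¹·h⁻¹ with all boundaries closed"),
            )

        _guard(results, "consistency", f"consistency_energy_cycle_{key}", energy)
    return results


def _biomass_results(model: Model, config: Config, cm) -> List[TestResult]:
    results: List[TestResult] = []
    candidates = biomass_mod.find_biomass_reactions(model)
    results.append(TestResult(
        test_id="biomass_presence", section="biomass",
        metric=1.0 if candidates else 0.0, data=list(candidates),
        message=f"{len(candidates)} biomass candidate reaction(s) found",
    ))
    if not candidates:
        for tid in ("biomass_consistency", "biomass_growth_default", "biomass_growth_complete",
                    "biomass_precursors_default", "biomass_precursors_complete",
                    "biomass_direct_precursors"):
            results.append(TestResult(test_id=tid, section="biomass", metric=None,
                                      message="no biomass reaction"))
        return results
    biomass_id = candidates[0]

    def weight():
        value = biomass_mod.biomass_weight(model, biomass_id)
        if value is None:
            return TestResult(test_id="biomass_consistency", section="biomass", metric=None,
                              message="biomass weight undetermined (incomplete formulas)")
        ok = abs(value - 1.0) <= config.biomass_tolerance
        return TestResult(
            test_id="biomass_consistency", section="biomass",
            metric=1.0 if ok else 0.0, data=[value],
            message=f"biomass weight {value:.6f} g·mmol⁻¹ (target 1.000)",
        )

    _guard(results, "biomass", "biomass_consistency", weight)

    for medium in ("default", "complete"):
        def growth(medium=medium):
            rate = biomass_mod.growth_rate(model, medium, config,
                                           biomass_id=biomass_id, cobra_model=cm)
            return TestResult(
                test_id=f"biomass_growth_{medium}", section="biomass",
                metric=1.0 if rate > config.eps_growth else 0.0, data=[rate],
                message=f"maximum growth rate {rate:.6g} h⁻¹ in {medium} medium",
            )

        _guard(results, "biomass", f"biomass_growth_{medium}", growth)

    for medium in ("default", "complete"):
        def precursors(medium=medium):
            flags = biomass_mod.precursor_production(model, biomass_id, medium, config,
                                                     cobra_model=cm)
            if not flags:
                return TestResult(test_id=f"biomass_precursors_{medium}", section="biomass",
                                  metric=None, message="biomass reaction has no substrates")
            failing = sorted(m for m, ok in flags.items() if not ok)
            return TestResult(
                test_id=f"biomass_precursors_{medium}", section="biomass",
                metric=1.0 - len(failing) / len(flags), data=failing,
                message=(f"{len(failing)} of {len(flags)} biomass precursors not "
                         f"producible in {medium} medium"),
            )

        _guard(results, "biomass", f"biomass_precursors_{medium}", precursors)

    def direct():
        ids = biomass_mod.direct_precursors(model, biomass_id)
        return TestResult(
            test_id="biomass_direct_precursors", section="biomass", metric=None,
            data=ids, scored=False,
            message=f"{len(ids)} biomass precursors supplied solely via boundary/transport",
        )

    _guard(results, "biomass", "biomass_direct_precursors", direct)
    return results


def _annotation_results(model: Model, config: Config) -> List[TestResult]:
    results: List[TestResult] = []
    registry = annotations_mod.build_registry(config)

    def xrefs():
        audits = annotations_mod.audit_cross_references(model, registry)
        out = []
        for klass in ("metabolite", "reaction", "gene"):
            audit = audits[klass]
            if audit.total == 0:
                out.append(TestResult(
                    test_id=f"annotation_{klass}_xref_presence", section="annotation",
                    metric=None, message=f"no {klass}s"))
                for namespace in sorted(registry[klass]):
                    out.append(TestResult(
                        test_id=f"annotation_{klass}_{namespace}", section="annotation",
                        metric=None, message=f"no {klass}s"))
                continue
            out.append(TestResult(
                test_id=f"annotation_{klass}_xref_presence", section="annotation",
                metric=1.0 - len(audit.missing_any) / audit.total,
                data=audit.missing_any,
                message=(f"{len(audit.missing_any)} of {audit.total} {klass}s carry "
                         "no cross-references at all"),
            ))
            for namespace in sorted(registry[klass]):
                ns_audit = audit.namespaces[namespace]
                offenders = sorted(set(ns_audit.missing) | set(ns_audit.invalid))
                out.append(TestResult(
                    test_id=f"annotation_{klass}_{namespace}", section="annotation",
                    metric=1.0 - len(offenders) / audit.total, data=offenders,
                    message=(f"{namespace}: {len(ns_audit.missing)} missing, "
                             f"{len(ns_audit.invalid)} invalid of {audit.total}"),
                ))
        return out

    _guard(results, "annotation", "annotation_xrefs", xrefs)

    def namespace_consistency():
        consistency = annotations_mod.primary_namespace_consistency(model, registry)
        out = []
        for klass in ("metabolite", "reaction", "gene"):
            if klass not in consistency:
                out.append(TestResult(
                    test_id=f"annotation_{klass}_namespace_consistency",
                    section="annotation", metric=None, message=f"no {klass}s"))
                continue
            namespace, fraction = consistency[klass]
            out.append(TestResult(
                test_id=f"annotation_{klass}_namespace_consistency", section="annotation",
                metric=fraction, data=[namespace],
                message=(f"best-matching namespace {namespace!r} covers "
                         f"{fraction:.1%} of native {klass} ids"),
            ))
        return out

    _guard(results, "annotation", "annotation_namespace_consistency", namespace_consistency)
    _guard(results, "annotation", "annotation_sbo",
           lambda: annotations_mod.sbo_coverage(model, config))
    return results


def _experimental_results(model: Model, config: Config, experiments) -> List[TestResult]:
    media, growth_obs, ess_obs = experiments
    results: List[TestResult] = []
    if growth_obs:
        def growth():
            outcome = experimental_mod.evaluate_growth(model, media, growth_obs, config)
            return TestResult(
                test_id="experimental_growth", section="experimental",
                metric=outcome.accuracy, data=[outcome.confusion],
                message=(f"growth accuracy {outcome.accuracy}, "
                         f"MCC {outcome.matthews}"),
            )

        _guard(results, "experimental", "experimental_growth", growth)
    if ess_obs:
        def essentiality():
            outcome = experimental_mod.evaluate_essentiality(model, ess_obs, media, config)
            return TestResult(
                test_id="experimental_essentiality", section="experimental",
                metric=outcome.accuracy, data=[outcome.confusion],
                message=(f"essentiality accuracy {outcome.accuracy}, "
                         f"MCC {outcome.matthews}"),
            )

        _guard(results, "experimental", "experimental_essentiality", essentiality)
    return results


def run_suite(model: Model, config: Optional[Config] = None,
              experiments: Optional[Tuple] = None) -> ResultSet:
    """Execute every applicable QC test and return the collected results.

    ``experiments`` is the triple returned by
    :func:`gemaudit.experimental.load_experiment_config` (or ``None``).
    """
    config = config or Config()
    results: List[TestResult] = []
    results.extend(basic_mod.test_components_present(model))
    results.extend(basic_mod.test_formula_and_charge(model))
    results.append(basic_mod.test_gpr_presence(model))
    results.append(basic_mod.metabolic_coverage(model))
    cm = to_cobra(model)
    results.extend(_consistency_results(model, config, cm))
    results.extend(_biomass_results(model, config, cm))
    results.extend(_annotation_results(model, config))
    if experiments is not None:
        results.extend(_experimental_results(model, config, experiments))
    return ResultSet(
        model_id=model.id,
        digest=model_digest(model),
        results=results,
        tool_version=TOOL_VERSION,
    )
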