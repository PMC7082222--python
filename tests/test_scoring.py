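"""Score condensation and report rendering."""

import random

import pytest

from gemaudit.config import Config
from gemaudit.report import diff_report, history_report, snapshot_report
from gemaudit.results import ResultSet, TestResult
from gemaudit.scoring import compute_score


def _result_set(results):
    return ResultSet(model_id="toy", digest="0" * 64, results=results)


def _tr(test_id, section, metric, weight=1.0, scored=True):
    return TestResult(test_id=test_id, section=section, metric=metric,
                      weight=weight, scored=scored)


def test_all_pass_scores_100():
    rs = _result_set([_tr(f"t{i}", s, 1.0) for i, s in
                      enumerate(["basic", "biomass", "consistency", "annotation"])])
    assert compute_score(rs).overall == pytest.approx(100.0)


def test_all_fail_scores_0():
    rs = _result_set([_tr(f"t{i}", s, 0.0) for i, s in
                      enumerate(["basic", "biomass", "consistency", "annotation"])])
    assert compute_score(rs).overall == pytest.approx(0.0)


def test_two_section_weighting():
    """Sections weighted 3 (score 100) and 1 (score 0) give overall 75."""
    rs = _result_set([_tr("t1", "consistency", 1.0), _tr("t2", "basic", 0.0)])
    breakdown = compute_score(rs)
    assert breakdown.sections == {"consistency": 100.0, "basic": 0.0}
    assert breakdown.overall == pytest.approx(75.0)


def test_per_test_weights_within_section():
    """An SBO test (weight 2) pulls the annotation section harder than a
    cross-reference test (weight 1)."""
    rs = _result_set([
        _tr("annotation_sbo_metabolites", "annotation", 0.0, weight=2.0),
        _tr("annotation_metabolite_chebi", "annotation", 1.0),
    ])
    assert compute_score(rs).sections["annotation"] == pytest.approx(100.0 / 3)


def test_stoichiometric_consistency_triple_weight():
    rs = _result_set([
        _tr("consistency_stoichiometric", "consistency", 0.0, weight=3.0),
        _tr("consistency_blocked_reactions", "consistency", 1.0),
    ])
    assert compute_score(rs).sections["consistency"] == pytest.approx(25.0)


def test_unscored_excluded():
    rs = _result_set([_tr("t1", "basic", 1.0), _tr("t2", "basic", None, scored=False)])
    breakdown = compute_score(rs)
    assert breakdown.overall == pytest.approx(100.0)
    assert breakdown.unscored_tests == ["t2"]


def test_all_unscored_is_undefined():
    rs = _result_set([_tr("t1", "basic", None, scored=False)])
    breakdown = compute_score(rs)
    assert breakdown.overall is None and not breakdown.defined


def test_permutation_invariance():
    results = [_tr(f"t{i}", s, m, w) for i, (s, m, w) in enumerate([
        ("basic", 0.5, 1.0), ("basic", 1.0, 2.0), ("consistency", 0.25, 3.0),
        ("annotation", 0.75, 1.0), ("biomass", 1.0, 1.0)])]
    base = compute_score(_result_set(results)).overall
    rng = random.Random(42)
    for _ in range(5):
        shuffled = results[:]
        rng.shuffle(shuffled)
        assert compute_score(_result_set(shuffled)).overall == pytest.approx(base)


def test_configurable_weights():
    config = Config()
    config.section_weights["basic"] = 9.0
    config.test_weights["t1"] = 5.0
    rs = _result_set([_tr("t1", "basic", 0.0), _tr("t2", "basic", 1.0),
                      _tr("t3", "consistency", 1.0)])
    breakdown = compute_score(rs, config)
    assert breakdown.sections["basic"] == pytest.approx(100.0 / 6)
    assert breakdown.overall == pytest.approx((9 * 100 / 6 + 3 * 100) / 12)


def test_empty_result_set_raises():
    with pytest.raises(ValueError):
        compute_score(_result_set([]))


def test_overall_range_and_perfection(textbook_resultset):
    breakdown = compute_score(textbook_resultset)
    assert 0.0 <= breakdown.overall <= 100.0
    scored = [r for r in textbook_resultset.results if r.scored]
    assert (breakdown.overall == pytest.approx(100.0)) == all(
        r.metric == 1.0 for r in scored)


# -- reports ---------------------------------------------------------------

def test_snapshot_contains_score_and_tests(textbook_resultset):
    document = snapshot_report(textbook_resultset)
    assert "100.0" in document.html
    for result in textbook_resultset.results:
        assert result.test_id in document.html
    round_tripped = ResultSet.from_dict(document.data["result_set"])
    assert round_tripped.to_dict() == textbook_resultset.to_dict()


def test_snapshot_deterministic(textbook_resultset):
    a = snapshot_report(textbook_resultset)
    b = snapshot_report(textbook_resultset)
    assert a.html == b.html and a.data == b.data


def test_diff_identical_models_no_deltas(textbook_resultset):
    document = diff_report([textbook_resultset, textbook_resultset])
    assert document.data["changed_tests"] == []


def test_diff_highlights_exactly_affected_tests(textbook, textbook_resultset):
    from gemaudit.fixtures import plant_defect
    from gemaudit.suite import run_suite

    model, manifest = textbook
    planted, new_manifest = plant_defect(model, manifest, "strip_gpr")
    planted_rs = run_suite(planted)
    document = diff_report([textbook_resultset, planted_rs])
    assert set(document.data["changed_tests"]) == new_manifest.expected_degraded_tests


def test_diff_three_columns(textbook_resultset):
    document = diff_report([textbook_resultset] * 3)
    assert len(document.data["models"]) == 3
    assert all(len(v) == 3 for v in document.data["metrics"].values())


def test_diff_requires_two(textbook_resultset):
    with pytest.raises(ValueError):
        diff_report([textbook_resultset])


def test_history_single_point(textbook_resultset):
    document = history_report([textbook_resultset])
    assert len(document.data["trajectory"]) == 1


def test_history_monotone_over_fix_sequence(textbook):
    """Fixing planted defects one by one yields a non-decreasing score."""
    from gemaudit.fixtures import plant_defect
    from gemaudit.suite import run_suite

    model, manifest = textbook
    two, m2 = plant_defect(model, manifest, "strip_gpr")
    two, m2 = plant_defect(two, m2, "strip_sbo")
    one, _ = plant_defect(model, manifest, "strip_gpr")
    sets = [run_suite(two), run_suite(one), run_suite(model)]
    document = history_report(sets, ordered=True)
    overalls = [p["overall"] for p in document.data["trajectory"]]
    assert overalls == sorted(overalls)


def test_history_collapses_duplicate_digests(textbook_resultset):
    document = history_report([textbook_resultset, textbook_resultset], ordered=True)
    assert document.data["collapsed_duplicates"] == 1
    assert len(document.data["trajectory"]) == 1


def test_resultset_json_roundtrip(textbook_resultset):
    text = textbook_resultset.to_json()
    assert ResultSet.from_json(text).to_dict() == textbook_resultset.to_dict()
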