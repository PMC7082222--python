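"""Annotation battery: cross-references, namespaces, SBO coverage."""

import pytest

from gemaudit.annotations import (
    audit_cross_references,
    build_registry,
    primary_namespace_consistency,
    sbo_coverage,
)
from gemaudit.model import SBO_METABOLIC_REACTION


def test_fixture_fully_annotated(textbook_model):
    audits = audit_cross_references(textbook_model)
    for audit in audits.values():
        assert audit.missing_any == []
        for ns_audit in audit.namespaces.values():
            assert ns_audit.missing == []
            assert ns_audit.invalid == []


def test_chebi_pattern_anchored(textbook_model):
    tweaked = textbook_model.copy()
    tweaked.metabolite("glc_c").annotations["chebi"] = ["17234"]  # bare number: invalid
    audit = audit_cross_references(tweaked)["metabolite"]
    assert audit.namespaces["chebi"].invalid == ["glc_c"]
    assert "glc_c" not in audit.namespaces["chebi"].missing


def test_zero_annotations(build):
    model = build(["a_c", "b_c"], [("R1", {"a_c": -1, "b_c": 1}, 0, 10)], genes=["g1"])
    audits = audit_cross_references(model)
    assert audits["metabolite"].missing_any == ["a_c", "b_c"]
    assert audits["reaction"].missing_any == ["R1"]
    assert audits["gene"].missing_any == ["g1"]


def test_removing_one_annotation_lowers_exactly_one_namespace(textbook_model):
    before = audit_cross_references(textbook_model)["metabolite"]
    tweaked = textbook_model.copy()
    del tweaked.metabolite("glc_c").annotations["hmdb"]
    after = audit_cross_references(tweaked)["metabolite"]
    changed = [ns for ns in before.namespaces
               if (before.namespaces[ns].missing, before.namespaces[ns].invalid)
               != (after.namespaces[ns].missing, after.namespaces[ns].invalid)]
    assert changed == ["hmdb"]
    assert after.namespaces["hmdb"].missing == ["glc_c"]


def test_namespace_consistency_on_fixture(textbook_model):
    consistency = primary_namespace_consistency(textbook_model)
    assert consistency["metabolite"] == ("bigg.metabolite", 1.0)
    assert consistency["reaction"] == ("bigg.reaction", 1.0)
    assert consistency["gene"] == ("uniprot", 1.0)


def test_namespace_consistency_fractured(build):
    """Half UniProt-shaped, half NCBI-gene-shaped ids: best coverage is 0.5."""
    model = build([], [], genes=["P12345", "P67890", "944175", "944176"])
    namespace, fraction = primary_namespace_consistency(model)["gene"]
    assert fraction == pytest.approx(0.5)
    assert namespace in ("uniprot", "ncbigene")


def test_namespace_consistency_no_match(build):
    model = build([], [], genes=["locus tag!", "???"])
    namespace, fraction = primary_namespace_consistency(model)["gene"]
    assert (namespace, fraction) == (None, 0.0)


def test_registry_override(build):
    from gemaudit.config import Config

    config = Config()
    config.registry_overrides = {"gene": {"locus": r"b\d{4}"}}
    registry = build_registry(config)
    assert "locus" in registry["gene"]
    assert registry["gene"]["locus"].fullmatch("b0001")


def test_sbo_full_coverage(textbook_model):
    results = {r.test_id: r for r in sbo_coverage(textbook_model)}
    assert all(r.metric == 1.0 for r in results.values())
    assert all(r.weight == 2.0 for r in results.values())


def test_sbo_wrong_biomass_term_counted(textbook_model):
    tweaked = textbook_model.copy()
    tweaked.reaction("BIOMASS").sbo = SBO_METABOLIC_REACTION  # should be 629
    result = {r.test_id: r for r in sbo_coverage(tweaked)}["annotation_sbo_reactions"]
    assert result.metric < 1.0
    assert "BIOMASS" in result.data


def test_sbo_untagged_model(build):
    model = build(["a_c"], [("R1", {"a_c": -1}, 0, 10)], genes=["g1"])
    results = {r.test_id: r for r in sbo_coverage(model)}
    assert results["annotation_sbo_metabolites"].metric == 0.0
    assert results["annotation_sbo_genes"].metric == 0.0


def test_audit_order_invariant(textbook_model):
    shuffled = textbook_model.copy()
    shuffled.metabolites = list(reversed(shuffled.metabolites))
    shuffled.reactions = list(reversed(shuffled.reactions))
    a = audit_cross_references(textbook_model)
    b = audit_cross_references(shuffled)
    for klass in a:
        assert a[klass].missing_any == b[klass].missing_any
        for ns in a[klass].namespaces:
            assert a[klass].namespaces[ns].missing == b[klass].namespaces[ns].missing
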