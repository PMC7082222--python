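"""Model containers, SBML I/O, sorted YAML, digests, GPR parsing."""

import pytest

from gemaudit.gpr import GPRError, eval_gpr, gpr_genes, parse_gpr
from gemaudit.model import Reaction, StructuralError, boundary_kind, is_boundary
from gemaudit.sbml import read_sbml, validate_structure, write_sbml
from gemaudit.yamlio import model_digest, sorted_yaml, write_sorted_yaml


# -- SBML round trip -------------------------------------------------------

def test_sbml_round_trip_preserves_content(textbook_model, tmp_path):
    """Write → read preserves stoichiometry, bounds, GPRs and annotations
    (checked via the order-insensitive canonical serialization)."""
    path = tmp_path / "model.xml"
    write_sbml(textbook_model, str(path))
    reread = read_sbml(str(path))
    assert model_digest(reread) == model_digest(textbook_model)


def test_read_missing_and_junk_files(tmp_path):
    with pytest.raises(StructuralError):
        read_sbml(str(tmp_path / "absent.xml"))
    junk = tmp_path / "junk.xml"
    junk.write_text("this is not xml <<<")
    with pytest.raises(StructuralError):
        read_sbml(str(junk))
    empty = tmp_path / "empty.xml"
    empty.write_text("")
    with pytest.raises(StructuralError):
        read_sbml(str(empty))


# -- structural validation -------------------------------------------------

def _fixture_xml(textbook_model, tmp_path):
    path = tmp_path / "clean.xml"
    write_sbml(textbook_model, str(path))
    return path.read_text()


def test_validate_clean_fixture(textbook_model, tmp_path):
    path = tmp_path / "clean.xml"
    write_sbml(textbook_model, str(path))
    assert validate_structure(str(path)) == []


def test_validate_duplicate_species_id(textbook_model, tmp_path):
    text = _fixture_xml(textbook_model, tmp_path)
    extra = ('<species id="M_glc_c" compartment="c" hasOnlySubstanceUnits="false" '
             'boundaryCondition="false" constant="false"/>')
    (tmp_path / "dup.xml").write_text(
        text.replace("</listOfSpecies>", extra + "</listOfSpecies>", 1))
    issues = validate_structure(str(tmp_path / "dup.xml"))
    assert any(i.severity == "error" and i.element_id == "M_glc_c" for i in issues)


def test_validate_dangling_species_reference(textbook_model, tmp_path):
    text = _fixture_xml(textbook_model, tmp_path)
    (tmp_path / "dangling.xml").write_text(
        text.replace('species="M_glc_c"', 'species="M_ghost_c"', 1))
    issues = validate_structure(str(tmp_path / "dangling.xml"))
    assert any(i.code == "dangling-species-reference" for i in issues)


def test_validate_unparseable(tmp_path):
    bad = tmp_path / "bad.xml"
    bad.write_text("not xml at all")
    issues = validate_structure(str(bad))
    assert issues and all(i.severity == "error" for i in issues)


# -- sorted YAML and digest ------------------------------------------------

def test_sorted_yaml_deterministic(textbook_model, tmp_path):
    p1, p2 = tmp_path / "a.yml", tmp_path / "b.yml"
    write_sorted_yaml(textbook_model, str(p1))
    write_sorted_yaml(textbook_model, str(p2))
    assert p1.read_bytes() == p2.read_bytes()


def test_sorted_yaml_order_invariant(textbook_model):
    shuffled = textbook_model.copy()
    shuffled.reactions = list(reversed(shuffled.reactions))
    shuffled.metabolites = list(reversed(shuffled.metabolites))
    assert sorted_yaml(shuffled) == sorted_yaml(textbook_model)
    assert model_digest(shuffled) == model_digest(textbook_model)


def test_yaml_reaction_ids_lexicographic(textbook_model):
    text = sorted_yaml(textbook_model)
    rxn_section = text.split("reactions:")[1].split("genes:")[0]
    ids = [line.split("id:")[1].strip() for line in rxn_section.splitlines()
           if line.strip().startswith("- id:")]
    assert ids == sorted(ids)


def test_digest_sensitive_to_bounds(textbook_model):
    tweaked = textbook_model.copy()
    tweaked.reaction("HEX1").upper_bound = 999.0
    assert model_digest(tweaked) != model_digest(textbook_model)


# -- boundary detection ----------------------------------------------------

@pytest.mark.parametrize(
    "rxn, kind",
    [
        (Reaction(id="R1", stoichiometry={"a_c": -1, "b_c": 1}, sbo="SBO:0000627"), "exchange"),
        (Reaction(id="R2", stoichiometry={"a_c": -1, "b_c": 1}, sbo="SBO:0000628"), "demand"),
        (Reaction(id="R3", stoichiometry={"a_c": -1, "b_c": 1}, sbo="SBO:0000632"), "sink"),
        (Reaction(id="EX_a", stoichiometry={"a_e": -1}), "exchange"),
        (Reaction(id="dm_a", stoichiometry={"a_c": -1}), "demand"),
        (Reaction(id="SK_a", stoichiometry={"a_c": -1}), "sink"),
        (Reaction(id="weird", stoichiometry={"a_c": -1}), "exchange"),
        (Reaction(id="EX_like", stoichiometry={"a_c": -1, "b_c": 1}), "exchange"),
        (Reaction(id="core", stoichiometry={"a_c": -1, "b_c": 1}), None),
    ],
)
def test_boundary_detection(rxn, kind):
    assert boundary_kind(rxn) == kind
    assert is_boundary(rxn) is (kind is not None)


# -- GPR grammar -----------------------------------------------------------

def test_gpr_parse_and_eval():
    tree = parse_gpr("(g1 and g2) or g3")
    assert gpr_genes(tree) == {"g1", "g2", "g3"}
    assert eval_gpr(tree, set())
    assert eval_gpr(tree, {"g1"})          # g3 still active
    assert not eval_gpr(tree, {"g1", "g3"})
    assert not eval_gpr(tree, {"g2", "g3"})


def test_gpr_case_and_whitespace_insensitive():
    a = parse_gpr("g1 AND  ( g2 OR g3 )")
    b = parse_gpr("g1 and (g2 or g3)")
    assert a == b


@pytest.mark.parametrize("bad", ["", "and", "g1 and", "(g1", "g1 or or g2", "g1 g2"])
def test_gpr_malformed(bad):
    with pytest.raises(GPRError):
        parse_gpr(bad)


def test_model_integrity_checks(build):
    model = build(
        ["a_c", "b_c"],
        [("R1", {"a_c": -1, "ghost_c": 1}, 0, 10), ("R2", {"b_c": -1}, 5, 1)],
    )
    problems = model.check_integrity()
    assert any("ghost_c" in p for p in problems)
    assert any("lower_bound > upper_bound" in p for p in problems)
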