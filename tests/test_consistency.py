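"""Stoichiometry battery: conservation LP, balance, blocked, orphans, EGC."""

import pytest

from gemaudit.config import Config
from gemaudit.consistency import (
    check_mass_charge_balance,
    detect_energy_generating_cycle,
    find_blocked_reactions,
    find_orphans_and_dead_ends,
    find_unconserved_metabolites,
)
from gemaudit.fixtures import make_random_network, plant_defect
from gemaudit.oracles import fva_blocked_oracle, unconserved_subset_oracle


# -- stoichiometric consistency -------------------------------------------

def test_linear_pathway_is_consistent(build):
    model = build(["a_c", "b_c", "c_c"],
                  [("R1", {"a_c": -1, "b_c": 1}, 0, 10),
                   ("R2", {"b_c": -1, "c_c": 1}, 0, 10),
                   ("EX_c", {"c_c": -1}, -10, 10)])
    cert = find_unconserved_metabolites(model)
    assert cert.unconserved == []
    assert cert.consistent


def test_mass_creating_loop_is_unconserved(build):
    """A pair of reactions that nets A -> 2A forces A's mass to zero."""
    model = build(["a_c", "b_c"],
                  [("R1", {"a_c": -1, "b_c": 2}, 0, 10),
                   ("R2", {"b_c": -1, "a_c": 1}, 0, 10),
                   ("EX_a", {"a_c": -1}, -10, 10)])
    cert = find_unconserved_metabolites(model)
    assert cert.unconserved == ["a_c", "b_c"]


def test_no_internal_reactions_trivially_consistent(build):
    model = build(["a_c"], [("EX_a", {"a_c": -1}, -10, 10)])
    assert find_unconserved_metabolites(model).unconserved == []


def test_scale_invariance_of_unconserved_set(textbook_model):
    scaled = textbook_model.copy()
    rxn = scaled.reaction("GLYC")
    rxn.stoichiometry = {m: 2 * c for m, c in rxn.stoichiometry.items()}
    assert (find_unconserved_metabolites(scaled).unconserved
            == find_unconserved_metabolites(textbook_model).unconserved)


@pytest.mark.parametrize("seed", range(8))
def test_matches_exhaustive_subset_oracle(seed):
    net = make_random_network(seed)
    assert find_unconserved_metabolites(net).unconserved == unconserved_subset_oracle(net)


# -- mass / charge balance -------------------------------------------------

def test_balanced_reaction(build):
    model = build([("h2o_c", "H2O", 0), ("h2_c", "H2", 0), ("o2_c", "O2", 0)],
                  [("R1", {"h2o_c": -2, "h2_c": 2, "o2_c": 1}, -10, 10)])
    balance = check_mass_charge_balance(model).reactions["R1"]
    assert balance.status == "balanced"
    assert balance.element_imbalance == {}
    assert balance.charge_imbalance == 0


def test_unbalanced_reaction_reports_net_imbalance(build):
    model = build([("a_c", "C", 0), ("b_c", "C2", 0)],
                  [("R1", {"a_c": -1, "b_c": 1}, 0, 10)])
    balance = check_mass_charge_balance(model).reactions["R1"]
    assert balance.mass_status == "unbalanced"
    assert balance.element_imbalance == {"C": 1}


def test_missing_formula_is_undetermined(build):
    model = build([("a_c", None, 0), ("b_c", "C2", 0)],
                  [("R1", {"a_c": -1, "b_c": 1}, 0, 10)])
    balance = check_mass_charge_balance(model).reactions["R1"]
    assert balance.mass_status == "undetermined"
    assert balance.charge_status == "balanced"


def test_boundary_reactions_excluded(build):
    model = build([("a_c", "C", 0)], [("EX_a", {"a_c": -1}, -10, 10)])
    assert check_mass_charge_balance(model).reactions == {}


def test_fixture_fully_balanced(textbook_model):
    report = check_mass_charge_balance(textbook_model)
    assert all(b.status == "balanced" for b in report.reactions.values())


def test_consistent_model_with_formulas_has_no_unbalanced(textbook_model):
    """Stoichiometric consistency + complete formulas ⇒ zero element-unbalanced
    internal reactions."""
    assert find_unconserved_metabolites(textbook_model).unconserved == []
    report = check_mass_charge_balance(textbook_model)
    assert not [b for b in report.reactions.values() if b.mass_status == "unbalanced"]


# -- blocked reactions -----------------------------------------------------

def test_open_pathway_not_blocked(build):
    model = build(["a_c", "b_c"],
                  [("EX_a", {"a_c": -1}, -10, 10),
                   ("R1", {"a_c": -1, "b_c": 1}, 0, 10),
                   ("EX_b", {"b_c": -1}, 0, 10)])
    assert find_blocked_reactions(model) == []


def test_dead_end_reaction_blocked(build):
    model = build(["a_c", "b_c", "d_c"],
                  [("EX_a", {"a_c": -1}, -10, 10),
                   ("R1", {"a_c": -1, "b_c": 1}, 0, 10),
                   ("EX_b", {"b_c": -1}, 0, 10),
                   ("R2", {"a_c": -1, "d_c": 1}, 0, 10)])
    assert find_blocked_reactions(model) == ["R2"]


def test_blocked_matches_fva_oracle_on_planted_fixture(textbook):
    model, manifest = textbook
    planted, new_manifest = plant_defect(model, manifest, "blocked_subnetwork")
    impl = find_blocked_reactions(planted)
    assert impl == fva_blocked_oracle(planted)
    assert impl == new_manifest.ground_truth["blocked"]
    assert set(impl) == {"DEFECT_BLK1", "DEFECT_BLK2"}


# -- orphans and dead ends -------------------------------------------------

def test_dead_end_detected(build):
    model = build(["a_e", "a_c", "b_c", "c_c"],
                  [("EX_a", {"a_e": -1}, -10, 10),
                   ("At", {"a_e": -1, "a_c": 1}, -10, 10),
                   ("R1", {"a_c": -1, "b_c": 1}, 0, 10),
                   ("R2", {"b_c": -1, "c_c": 1}, 0, 10)])
    orphans, dead_ends = find_orphans_and_dead_ends(model)
    assert "c_c" in dead_ends
    assert "c_c" not in orphans


def test_orphan_detected(build):
    model = build(["a_c", "b_c"],
                  [("R1", {"a_c": -1, "b_c": 1}, 0, 10), ("EX_b", {"b_c": -1}, 0, 10)])
    orphans, _ = find_orphans_and_dead_ends(model)
    assert "a_c" in orphans


def test_reversible_cycle_has_none(build):
    model = build(["a_c", "b_c"],
                  [("R1", {"a_c": -1, "b_c": 1}, -10, 10),
                   ("R2", {"b_c": -1, "a_c": 1}, -10, 10)])
    assert find_orphans_and_dead_ends(model) == ([], [])


def test_fixture_has_no_orphans_or_dead_ends(textbook_model):
    assert find_orphans_and_dead_ends(textbook_model) == ([], [])


# -- energy-generating cycles ---------------------------------------------

def test_healthy_fixture_dissipates_nothing(textbook_model):
    config = Config()
    for key in ("atp", "nadh"):
        result = detect_energy_generating_cycle(textbook_model, key, config)
        assert result.dissipation_flux == pytest.approx(0.0, abs=config.eps_flux)
        assert not result.has_cycle()


def test_planted_gratis_atp_detected(textbook):
    model, manifest = textbook
    planted, _ = plant_defect(model, manifest, "energy_generating_cycle")
    result = detect_energy_generating_cycle(planted, "atp")
    assert result.has_cycle()
    assert "DEFECT_ATPGEN" in result.cycle_reactions


def test_absent_species_unscored(textbook_model):
    result = detect_energy_generating_cycle(textbook_model, "gtp")
    assert result.dissipation_flux is None


def test_unknown_key_raises(textbook_model):
    with pytest.raises(KeyError):
        detect_energy_generating_cycle(textbook_model, "unobtainium")


def test_dissipation_monotone_under_reaction_addition(textbook):
    """Adding the gratis reaction can only increase the dissipation optimum
    (the feasible region grows, exchanges stay closed)."""
    model, manifest = textbook
    before = detect_energy_generating_cycle(model, "atp").dissipation_flux
    planted, _ = plant_defect(model, manifest, "energy_generating_cycle")
    after = detect_energy_generating_cycle(planted, "atp").dissipation_flux
    assert after >= before - 1e-9
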