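"""Experimental validation: config loading, growth and essentiality tests."""

import pandas as pd
import pytest
import yaml

from gemaudit.experimental import (
    ConfigError,
    EssentialityObservation,
    GrowthObservation,
    Medium,
    evaluate_essentiality,
    evaluate_growth,
    load_experiment_config,
)

GLUCOSE_ROWS = [
    ("EX_glc_e", -10, 1000), ("EX_o2_e", -1000, 1000), ("EX_nh4_e", -1000, 1000),
    ("EX_pi_e", -1000, 1000), ("EX_h2o_e", -1000, 1000), ("EX_h_e", -1000, 1000),
    ("EX_pyr_e", 0, 1000),
]


def _write_manifest(tmp_path, growth_file="growth.csv"):
    media = pd.DataFrame(GLUCOSE_ROWS, columns=["exchange", "lower", "upper"])
    media.to_csv(tmp_path / "glucose.csv", index=False)
    carbon_free = media[media.exchange != "EX_glc_e"]
    carbon_free.to_csv(tmp_path / "carbonfree.csv", index=False)
    growth = pd.DataFrame([("glucose", "TRUE"), ("carbonfree", "no")],
                          columns=["medium", "growth"])
    growth.to_csv(tmp_path / "growth.csv", index=False)
    growth.to_csv(tmp_path / "growth.tsv", sep="\t", index=False)
    growth.to_excel(tmp_path / "growth.xlsx", index=False)
    manifest = {
        "version": 1,
        "media": {"glucose": {"filename": "glucose.csv"},
                  "carbonfree": {"filename": "carbonfree.csv"}},
        "growth": [{"filename": growth_file}],
    }
    path = tmp_path / "experiments.yml"
    path.write_text(yaml.safe_dump(manifest))
    return path


def test_load_growth_table(tmp_path):
    media, growth, essentiality = load_experiment_config(str(_write_manifest(tmp_path)))
    assert sorted(media) == ["carbonfree", "glucose"]
    assert [(o.medium, o.observed_growth) for o in growth] == [
        ("glucose", True), ("carbonfree", False)]
    assert essentiality == []


@pytest.mark.parametrize("ext", ["tsv", "xlsx"])
def test_format_tolerance(tmp_path, ext):
    """csv, tsv and xlsx encodings of the same table parse identically."""
    baseline = load_experiment_config(str(_write_manifest(tmp_path)))[1]
    other = load_experiment_config(str(_write_manifest(tmp_path, f"growth.{ext}")))[1]
    assert [(o.medium, o.observed_growth) for o in other] == [
        (o.medium, o.observed_growth) for o in baseline]


def test_header_typo_is_config_error(tmp_path):
    pd.DataFrame([("glucose", "TRUE")], columns=["medium", "grwoth"]).to_csv(
        tmp_path / "growth.csv", index=False)
    (tmp_path / "m.yml").write_text(yaml.safe_dump(
        {"growth": [{"filename": "growth.csv"}]}))
    with pytest.raises(ConfigError, match="growth"):
        load_experiment_config(str(tmp_path / "m.yml"))


def test_bad_flag_is_config_error(tmp_path):
    pd.DataFrame([("glucose", "maybe")], columns=["medium", "growth"]).to_csv(
        tmp_path / "growth.csv", index=False)
    (tmp_path / "m.yml").write_text(yaml.safe_dump(
        {"growth": [{"filename": "growth.csv"}]}))
    with pytest.raises(ConfigError, match="maybe"):
        load_experiment_config(str(tmp_path / "m.yml"))


def test_missing_file_is_config_error(tmp_path):
    (tmp_path / "m.yml").write_text(yaml.safe_dump(
        {"growth": [{"filename": "nowhere.csv"}]}))
    with pytest.raises(ConfigError, match="not found"):
        load_experiment_config(str(tmp_path / "m.yml"))


def _media():
    return {
        "glucose": Medium("glucose", {r: (lo, hi) for r, lo, hi in GLUCOSE_ROWS}),
        "carbonfree": Medium("carbonfree", {r: (lo, hi) for r, lo, hi in GLUCOSE_ROWS
                                            if r != "EX_glc_e"}),
    }


def test_growth_agreement(textbook_model):
    observations = [GrowthObservation("glucose", True),
                    GrowthObservation("carbonfree", False)]
    outcome = evaluate_growth(textbook_model, _media(), observations)
    assert all(r.agreement for r in outcome.records)
    assert outcome.accuracy == 1.0


def test_growth_accuracy_three_of_four(textbook_model):
    observations = [GrowthObservation("glucose", True),
                    GrowthObservation("glucose", True),
                    GrowthObservation("carbonfree", False),
                    GrowthObservation("carbonfree", True)]  # deliberately wrong
    outcome = evaluate_growth(textbook_model, _media(), observations)
    assert outcome.accuracy == pytest.approx(0.75)


def test_unknown_medium_unevaluable(textbook_model):
    outcome = evaluate_growth(textbook_model, _media(),
                              [GrowthObservation("minimal", True)])
    assert outcome.records[0].predicted is None
    assert outcome.confusion["unevaluable"] == 1


def test_unknown_exchange_unevaluable(textbook_model):
    media = {"odd": Medium("odd", {"EX_unobtainium_e": (-10, 10)})}
    outcome = evaluate_growth(textbook_model, media, [GrowthObservation("odd", True)])
    assert outcome.records[0].predicted is None


def test_sole_catalyst_gene_essential(textbook_model):
    outcome = evaluate_essentiality(
        textbook_model, [EssentialityObservation("P10008", True)])
    assert outcome.records[0].predicted is True
    assert outcome.records[0].agreement is True


def test_isoenzyme_pair_not_essential(textbook_model):
    for gene in ("P10009", "P10010"):
        outcome = evaluate_essentiality(
            textbook_model, [EssentialityObservation(gene, False)])
        assert outcome.records[0].predicted is False


def test_unknown_gene_unevaluable(textbook_model):
    outcome = evaluate_essentiality(
        textbook_model, [EssentialityObservation("ghost", True)])
    assert outcome.records[0].predicted is None


def test_gpr_formatting_invariance(textbook_model):
    """Whitespace and keyword case in GPR rules do not change predictions."""
    reformatted = textbook_model.copy()
    reformatted.reaction("GLYC").gpr = "P10009   OR   P10010"
    reformatted.reaction("RESP").gpr = "( P10011 AND P10012 )"
    observations = [EssentialityObservation(g, False)
                    for g in ("P10009", "P10010", "P10011", "P10012")]
    a = [r.predicted for r in evaluate_essentiality(textbook_model, observations).records]
    b = [r.predicted for r in evaluate_essentiality(reformatted, observations).records]
    assert a == b


def test_knockout_never_increases_growth(textbook_model):
    """The wild-type optimum bounds every knockout optimum from above."""
    from gemaudit.oracles import fba_oracle
    from gemaudit import gpr as gpr_mod

    wild_type, _ = fba_oracle(textbook_model, {"BIOMASS": 1.0})
    for gene in textbook_model.genes:
        disabled = {}
        for rxn in textbook_model.reactions:
            if rxn.gpr and not gpr_mod.eval_gpr(gpr_mod.parse_gpr(rxn.gpr), {gene.id}):
                disabled[rxn.id] = (0.0, 0.0)
        optimum, _ = fba_oracle(textbook_model, {"BIOMASS": 1.0}, disabled)
        assert optimum is not None and optimum <= wild_type + 1e-9
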