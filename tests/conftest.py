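"""Shared fixtures: the textbook toy model and small model-building helpers."""

from __future__ import annotations

import pytest

from gemaudit.fixtures import make_textbook_model
from gemaudit.model import Gene, Metabolite, Model, Reaction
from gemaudit.suite import run_suite


@pytest.fixture(scope="session")
def textbook():
    """Healthy textbook fixture (model, manifest) — do not mutate; copy first."""
    return make_textbook_model(0)


@pytest.fixture(scope="session")
def textbook_model(textbook):
    return textbook[0]


@pytest.fixture(scope="session")
def textbook_manifest(textbook):
    return textbook[1]


@pytest.fixture(scope="session")
def textbook_resultset(textbook_model):
    return run_suite(textbook_model)


@pytest.fixture()
def model_copy(textbook_model):
    """Fresh mutable copy of the textbook model for defect-style edits."""
    return textbook_model.copy()


def build_model(metabolites, reactions, genes=(), compartments=None, objective=None):
    """Terse model builder for hand-written test networks.

    ``metabolites``: list of (id, formula, charge) or plain ids;
    ``reactions``: list of (id, stoichiometry, lb, ub) or
    (id, stoichiometry, lb, ub, gpr).
    """
    comps = compartments or {"c": "cytosol"}
    model = Model(id="testnet", compartments=comps)
    for entry in metabolites:
        if isinstance(entry, str):
            entry = (entry, None, None)
        mid, formula, charge = entry
        comp = mid.rsplit("_", 1)[-1] if mid.rsplit("_", 1)[-1] in comps else "c"
        model.metabolites.append(
            Metabolite(id=mid, name=mid, compartment=comp, formula=formula, charge=charge))
    for entry in reactions:
        rid, stoich, lb, ub = entry[:4]
        gpr = entry[4] if len(entry) > 4 else None
        model.reactions.append(Reaction(id=rid, name=rid, stoichiometry=dict(stoich),
                                        lower_bound=lb, upper_bound=ub, gpr=gpr))
    for gid in genes:
        model.genes.append(Gene(id=gid, name=gid))
    model.objective = dict(objective or {})
    return model


@pytest.fixture()
def build():
    return build_model
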