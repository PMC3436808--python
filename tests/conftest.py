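import pytest

from stoichcap.fixtures import krebs_fixture
from stoichcap.formulas import parse_formula
from stoichcap.model import MetabolicModel, Metabolite, Reaction


@pytest.fixture(scope="session")
def krebs():
    return krebs_fixture()


def make_chain(uptake: float = 5.0) -> MetabolicModel:
    """Linear chain Ext -> A -> B -> Ext with unit stoichiometry.

    The uptake bound is the only binding constraint, so the optimum, every
    optimal flux and every coupling coefficient are known by inspection.
    """
    mets = [
        Metabolite("A", formula=parse_formula("C6H12O6")),
        Metabolite("B", formula=parse_formula("C6H12O6")),
    ]
    rxns = [
        Reaction("UP", {"A": 1.0}, 0.0, uptake, is_boundary=True),
        Reaction("CONV", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
        Reaction("EXP", {"B": -1.0}, 0.0, 1000.0, is_boundary=True),
    ]
    return MetabolicModel(mets, rxns, {"EXP": 1.0}, "chain")


@pytest.fixture()
def chain():
    return make_chain()
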