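import pytest

from boftools.composition import load_composition
from boftools.constants import data_path


@pytest.fixture(scope="session")
def measured_composition():
    """The shipped E. coli K-12 exponential-growth composition table."""
    with data_path("ecoli_k12_mg1655_exponential.tsv") as path:
        return load_composition(path)


@pytest.fixture(scope="session")
def ecoli_template():
    """Bundled E. coli genome-scale template model (loaded once per session)."""
    from boftools.io import template_model

    return template_model()


def build_model(reactions, objective):
    """Toy cobra model from {rxn_id: (stoichiometry {met: coef}, lb, ub)}."""
    from cobra import Metabolite, Model, Reaction

    model = Model("toy")
    mets = {}
    for rxn_id, (stoich, lb, ub) in reactions.items():
        rxn = Reaction(rxn_id, lower_bound=lb, upper_bound=ub)
        rxn.add_metabolites(
            {
                mets.setdefault(m, Metabolite(m, compartment="c")): c
                for m, c in stoich.items()
            }
        )
        model.add_reactions([rxn])
    model.objective = objective
    return model


@pytest.fixture
def chain_model():
    """EX -> A -> B -> biomass, uptake capped at 10."""
    return build_model(
        {
            "EX_A": ({"A": 1}, 0, 10),
            "R_AB": ({"A": -1, "B": 1}, 0, 1000),
            "BIOMASS": ({"B": -1}, 0, 1000),
        },
        "BIOMASS",
    )


@pytest.fixture
def diamond_model():
    """Two parallel capacity-10 routes from A to B, demand fixed at 10."""
    return build_model(
        {
            "EX_A": ({"A": 1}, 0, 10),
            "R1": ({"A": -1, "B": 1}, 0, 10),
            "R2": ({"A": -1, "B": 1}, 0, 10),
            "BIOMASS": ({"B": -1}, 10, 10),
        },
        "BIOMASS",
    )
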