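import numpy as np
import pytest

from gemflux.core import MetabolicModel, Metabolite, Reaction
from gemflux.synth import ToyNetworkSpec, make_toy_model, toy_minimal_medium


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_model(ToyNetworkSpec(seed=0))


@pytest.fixture
def aerobic_hb3():
    return toy_minimal_medium(carbon="EX_hb3_e", aerobic=True)


@pytest.fixture
def aerobic_ttl():
    return toy_minimal_medium(carbon="EX_ttl_e", aerobic=True)


@pytest.fixture
def anaerobic_hb3():
    return toy_minimal_medium(carbon="EX_hb3_e", aerobic=False)


@pytest.fixture(scope="session")
def chain_model():
    """3-reaction linear chain with unit yield: source -> transport ->
    biomass; the FBA optimum is the source bound (analytic vertex)."""
    model = MetabolicModel(
        id="chain",
        metabolites=[Metabolite(id="s[e]", compartment="e"),
                     Metabolite(id="s[c]", compartment="c")],
        reactions=[
            Reaction(id="EX_s_e", stoichiometry={"s[e]": -1.0},
                     kind="exchange", lower_bound=-10.0, upper_bound=1000.0),
            Reaction(id="T_s", stoichiometry={"s[e]": -1.0, "s[c]": 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction(id="GROW", stoichiometry={"s[c]": -1.0},
                     kind="biomass", lower_bound=0.0, upper_bound=1000.0),
        ],
        genes=[],
        objectives={"biomass_aerobic": "GROW"})
    model.validate()
    return model


def random_flux_network(rng: np.random.Generator, n_reactions: int = 6,
                        n_metabolites: int = 3):
    """A random bounded network (all finite bounds straddling 0, so v = 0
    is feasible) as (model, objective reaction id)."""
    while True:
        S = rng.integers(-2, 3, size=(n_metabolites, n_reactions)).astype(float)
        if np.all(np.any(S != 0, axis=0)):
            break
    mets = [Metabolite(id=f"m{i}[c]") for i in range(n_metabolites)]
    rxns = []
    for j in range(n_reactions):
        stoich = {f"m{i}[c]": S[i, j] for i in range(n_metabolites)
                  if S[i, j] != 0}
        lb = float(rng.choice([-10.0, -5.0, 0.0]))
        ub = float(rng.choice([0.0, 5.0, 10.0]))
        if lb > ub:
            lb, ub = ub, lb
        kind = "internal" if len(stoich) >= 2 else "sink"
        rxns.append(Reaction(id=f"r{j}", stoichiometry=stoich,
                             lower_bound=lb, upper_bound=ub, kind=kind))
    obj = f"r{rng.integers(n_reactions)}"
    model = MetabolicModel(id="random", metabolites=mets, reactions=rxns,
                           genes=[], objectives={"obj": obj})
    model.validate()
    return model, obj
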