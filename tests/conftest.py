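import pytest

from mgeburden.core import MetabolicModel, Metabolite, Reaction
from mgeburden.synth import ToySpec, make_toy_host


@pytest.fixture
def chain_model():
    """Linear 3-reaction chain: bounded uptake of A, A->B, B->sink (objective).

    Unique optimum: every flux = 10, Z = 10 (hand vertex enumeration of the
    3-variable LP: the only vertex of the optimal face is (10, 10, 10)).
    """
    return MetabolicModel(
        metabolites=[Metabolite("A_c", compartment="c"),
                     Metabolite("B_c", compartment="c")],
        reactions=[
            Reaction("UP", {"A_c": 1}, 0, 10, is_exchange=True),
            Reaction("AB", {"A_c": -1, "B_c": 1}, 0, 1000),
            Reaction("SINK", {"B_c": -1}, 0, 1000, is_exchange=True),
        ],
        objective={"SINK": 1.0},
        id="chain")


@pytest.fixture
def parallel_model():
    """Two routes A->B: a direct reaction and a two-step detour via X.

    Both can carry the full uptake of 10, so FVA at 100% optimum gives each
    branch the range [0, 10]; pFBA picks the one-step route.
    """
    return MetabolicModel(
        metabolites=[Metabolite("A_c", compartment="c"),
                     Metabolite("X_c", compartment="c"),
                     Metabolite("B_c", compartment="c")],
        reactions=[
            Reaction("UP", {"A_c": 1}, 0, 10, is_exchange=True),
            Reaction("DIRECT", {"A_c": -1, "B_c": 1}, 0, 1000),
            Reaction("AX", {"A_c": -1, "X_c": 1}, 0, 1000),
            Reaction("XB", {"X_c": -1, "B_c": 1}, 0, 1000),
            Reaction("SINK", {"B_c": -1}, 0, 1000, is_exchange=True),
        ],
        objective={"SINK": 1.0},
        id="parallel")


@pytest.fixture(scope="session")
def toy_host():
    return make_toy_host(ToySpec(seed=1729))
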