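import numpy as np
import pytest

from procdesign.casestudies import (
    OSCILLATOR_LIBRARY,
    OSCILLATOR_MODEL,
    TOGGLE_LIBRARY,
    TOGGLE_MODEL,
)
from procdesign.enumerator import enumerate_candidates
from procdesign.formalism import (
    ConstSpec,
    parse_incomplete_model,
    parse_library,
)
from procdesign.network import MASS_ACTION, RateLaw, Reaction, ReactionNetwork


@pytest.fixture(scope="session")
def toggle_lib():
    return parse_library(TOGGLE_LIBRARY)


@pytest.fixture(scope="session")
def toggle_model(toggle_lib):
    return parse_incomplete_model(TOGGLE_MODEL, toggle_lib)


@pytest.fixture(scope="session")
def toggle_candidates(toggle_model, toggle_lib):
    return enumerate_candidates(toggle_model, toggle_lib)


@pytest.fixture(scope="session")
def osc_lib():
    return parse_library(OSCILLATOR_LIBRARY)


@pytest.fixture(scope="session")
def osc_model(osc_lib):
    return parse_incomplete_model(OSCILLATOR_MODEL, osc_lib)


@pytest.fixture(scope="session")
def osc_candidates(osc_model, osc_lib):
    return enumerate_candidates(osc_model, osc_lib)


def make_network(species, reactions, params, initial=None, name="test"):
    """Build a ReactionNetwork directly (bypassing the DSL) for
    simulator/objective unit tests."""
    net = ReactionNetwork(name=name)
    net.species = list(species)
    net.initial = {s: 0.0 for s in species}
    if initial:
        net.initial.update(initial)
    for reactants, products, law in reactions:
        if isinstance(law, str):
            law = RateLaw(MASS_ACTION, k=law)
        net.reactions.append(Reaction(tuple(reactants), tuple(products), law))
    for k, v in params.items():
        if isinstance(v, tuple):
            net.parameters[k] = ConstSpec(low=v[0], high=v[1])
        else:
            net.parameters[k] = ConstSpec(low=v, high=v, fixed=float(v))
    return net


@pytest.fixture
def decay_net():
    """A -> 0 at rate k (pure death)."""
    return make_network(
        ["A"], [([("A", 1)], [], "k")], {"k": 1.0}, initial={"A": 1.0}
    )


@pytest.fixture
def binding_net():
    """Reversible A + B <-> C."""
    return make_network(
        ["A", "B", "C"],
        [
            ([("A", 1), ("B", 1)], [("C", 1)], "kf"),
            ([("C", 1)], [("A", 1), ("B", 1)], "kb"),
        ],
        {"kf": 1.0, "kb": 0.5},
        initial={"A": 1.0, "B": 0.8, "C": 0.0},
    )


@pytest.fixture
def birth_death_net():
    """0 -> A at rate b, A -> 0 at rate d (linear network)."""
    return make_network(
        ["A"],
        [([], [("A", 1)], "b"), ([("A", 1)], [], "d")],
        {"b": 5.0, "d": 0.5},
        initial={"A": 0.0},
    )
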