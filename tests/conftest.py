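import numpy as np
import pytest

import endosig as es
from endosig.modelspec import ModelConfig, build_default_model
from endosig.network import ParameterSet, ReactionRule, SpeciesDef


@pytest.fixture(scope="session")
def params():
    return es.baseline_parameters()


@pytest.fixture(scope="session")
def model():
    return build_default_model()


@pytest.fixture(scope="session")
def compiled(model, params):
    return es.compile_rhs(model, params)


@pytest.fixture(scope="session")
def rest_state(compiled):
    """Ligand-free pre-equilibrated state of the full model."""
    return es.pre_equilibrate(compiled)


@pytest.fixture(scope="session")
def tie_model():
    return build_default_model(ModelConfig(subsystems=frozenset({"tie"})))


@pytest.fixture(scope="session")
def tie_compiled(tie_model, params):
    return es.compile_rhs(tie_model, params)


def make_binding_toy(kon=1.0, koff=1.0, a0=1.0, b0=1.0):
    """A + B <-> C, mass action; the closed-form workhorse."""
    species = [
        SpeciesDef("A", "cytosol", {"A": 1}, initial_value_key="A_0"),
        SpeciesDef("B", "cytosol", {"B": 1}, initial_value_key="B_0"),
        SpeciesDef("C", "cytosol", {"A": 1, "B": 1}),
    ]
    rules = [ReactionRule("bind", ("A", "B"), ("C",), "mass_action",
                          "kon", reversible=True, reverse_key="koff")]
    model = es.NetworkModel(species=species, rules=rules,
                            observables={"C": {"C": 1}})
    params = ParameterSet({"kon": kon, "koff": koff, "A_0": a0, "B_0": b0})
    return model, params
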