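import numpy as np
import pytest

from moanet.knowledge_base import (
    DrugCharacterization,
    DrugTarget,
    Effector,
    MotiveCharacterization,
    ProteinRef,
    Restriction,
    TruthTable,
)
from moanet.network_builder import Interactome
from moanet.propagation_model import compile_network
from moanet.synthetic_data import hemophilia_toy_scenario, signal_scenario


def make_interactome(edges, directed=False):
    """Edges as (u, v) or (u, v, sign) tuples."""
    inter = Interactome()
    for e in edges:
        u, v, *rest = e
        inter.add_edge(u, v, sign=(rest[0] if rest else 1), directed=directed)
    return inter


@pytest.fixture
def path_graph():
    """A - B - C - D chain, all activating."""
    return make_interactome([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture
def triangle():
    return make_interactome([("A", "B"), ("B", "C"), ("A", "C")])


def drug(name, *targets):
    """targets as (accession, action) pairs."""
    return DrugCharacterization(
        name, frozenset(DrugTarget(ProteinRef(a), s) for a, s in targets)
    )


def motive(name, *effectors):
    return MotiveCharacterization(
        name, frozenset(Effector(ProteinRef(a), d) for a, d in effectors)
    )


def restriction(stimulus, condition, relation="induces", label=True):
    return Restriction(
        stimulus=stimulus,
        condition=condition.name,
        response=condition.effectors,
        relation=relation,
        label=label,
    )


@pytest.fixture(scope="session")
def default_scenario():
    """The default planted-mechanism scenario (shared; treat as read-only)."""
    return signal_scenario(seed=1)


@pytest.fixture(scope="session")
def default_net(default_scenario):
    return compile_network(default_scenario.interactome)


@pytest.fixture(scope="session")
def toy_scenario():
    return hemophilia_toy_scenario(seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
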