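import numpy as np
import pytest

from ubn import (
    BnModel,
    Cpt,
    Evidence,
    NodeSpec,
    Query,
    build_network,
    generate_fixture,
)


@pytest.fixture
def chain_model() -> BnModel:
    """A -> B chain with hand-set tables (spec'd factors multiply to 0.15)."""
    a = NodeSpec("A", ("a1", "a2"))
    b = NodeSpec("B", ("b1", "b2"), parents=("A",))
    return build_network(
        [a, b],
        [
            Cpt("A", {(): (0.3, 0.7)}),
            Cpt("B", {("a1",): (0.5, 0.5), ("a2",): (0.2, 0.8)}),
        ],
    )


@pytest.fixture
def three_chain_model() -> BnModel:
    """A -> B -> C chain with fixed tables for evidence tests."""
    a = NodeSpec("A", ("a1", "a2"))
    b = NodeSpec("B", ("b1", "b2"), parents=("A",))
    c = NodeSpec("C", ("c1", "c2"), parents=("B",))
    return build_network(
        [a, b, c],
        [
            Cpt("A", {(): (0.6, 0.4)}),
            Cpt("B", {("a1",): (0.7, 0.3), ("a2",): (0.25, 0.75)}),
            Cpt("C", {("b1",): (0.1, 0.9), ("b2",): (0.8, 0.2)}),
        ],
    )


@pytest.fixture
def binary_root_model() -> BnModel:
    x = NodeSpec("X", ("x1", "x2"))
    return build_network([x], [Cpt("X", {(): (0.2, 0.8)})])


def random_model(seed: int, n_nodes: int = 5, max_states: int = 4,
                 density: float = 0.5) -> BnModel:
    model, _ = generate_fixture(n_nodes, max_states=max_states,
                                density=density, seed=seed)
    return model


def random_query(model: BnModel, rng: np.random.Generator,
                 with_evidence: bool = True) -> Query:
    names = list(model.node_names())
    target = names[rng.integers(len(names))]
    states = model.node(target).states
    k = int(rng.integers(1, len(states)))
    event = tuple(rng.choice(states, size=k, replace=False))
    evidence = []
    if with_evidence:
        for name in names:
            if name == target or rng.random() > 0.4:
                continue
            sts = model.node(name).states
            if rng.random() < 0.5:
                evidence.append(Evidence.hard(name, sts[rng.integers(len(sts))]))
            else:
                w = rng.uniform(0.05, 1.0, size=len(sts))
                evidence.append(Evidence.virtual(name, tuple(w)))
    return Query(target=target, event_states=event, evidence=tuple(evidence))
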