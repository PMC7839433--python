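"""Core domain types for discrete Bayesian networks in risk assessment.

A Bayesian network (BN) here is a directed acyclic graph of finite-state
chance nodes, each carrying one (conditional) probability table, together
with a tag stating which kind of uncertainty the node-state probabilities
express:

``epistemic``
    subjective degrees of belief about a unique event or unknown quantity
    (a genuine Bayesian belief network used for probabilistic reasoning);
``aleatory``
    best-estimate relative frequencies for a sampling event (variability);
``predictive``
    a marginal that mixes variability with parameter uncertainty in an
    unknown proportion.

The tag carries no computational weight — inference is identical for all
three — but it governs how results must be interpreted and communicated,
which is the whole point of keeping it explicit.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

ROW_SUM_TOL = 1e-9

BN_TYPES = ("epistemic", "aleatory", "predictive")


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class UbnError(Exception):
    """Base class for all errors raised by this package."""


class StructuralError(UbnError):
    """The directed graph is not a DAG, or references undeclared nodes."""


class NormalizationError(UbnError):
    """A table row does not sum to 1 within tolerance."""


class SchemaError(UbnError):
    """Missing or extra table rows, malformed documents, bad field values."""


class InputError(UbnError):
    """Invalid user input to a query or operation."""


class InconsistentEvidenceError(UbnError):
    """Conditioning event has zero probability under the model."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeSpec:
    """A finite-state chance node: an event, variable, or statement.

    Parameters
    ----------
    name : str
        Unique node identifier.
    states : tuple of str
        Ordered state labels, at least two, unique within the node.
    parents : tuple of str
        Ordered parent node names; the order fixes row-key addressing.
    meaning : str
        Free text describing what the node represents.
    """

    name: str
    states: tuple[str, ...]
    parents: tuple[str, ...] = ()
    meaning: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "parents", tuple(self.parents))
        if len(self.states) < 2:
            raise SchemaError(f"node {self.name!r} needs >=2 states, got {len(self.states)}")
        if len(set(self.states)) != len(self.states):
            raise SchemaError(f"node {self.name!r} has duplicate state labels")
        if self.name in self.parents:
            raise StructuralError(f"node {self.name!r} lists itself as a parent")


@dataclass(frozen=True)
class Cpt:
    """A (conditional) probability table: one probability vector over the
    node's states per parent-state configuration.

    Row keys are ordered tuples of parent states following the declared
    parent order; a parentless node has the single key ``()``.  The row
    entries are the table probabilities *t* that parameterize variability
    in an aleatory network.
    """

    node: str
    rows: Mapping[tuple[str, ...], tuple[float, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "rows",
            {tuple(k): tuple(float(p) for p in v) for k, v in self.rows.items()},
        )

    def validate(self, spec: NodeSpec, nodes: Mapping[str, NodeSpec]) -> None:
        expected = set(
            itertools.product(*(nodes[p].states for p in spec.parents))
        ) if spec.parents else {()}
        got = set(self.rows)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise SchemaError(
                f"CPT for {self.node!r}: missing rows {missing[:3]}, extra rows {extra[:3]} "
                f"(expected {len(expected)} rows, got {len(got)})"
            )
        k = len(spec.states)
        for key, row in self.rows.items():
            if len(row) != k:
                raise SchemaError(
                    f"CPT for {self.node!r} row {key}: {len(row)} entries for {k} states"
                )
            if any(p < -ROW_SUM_TOL or p > 1 + ROW_SUM_TOL for p in row):
                raise NormalizationError(
                    f"CPT for {self.node!r} row {key}: entries outside [0, 1]: {row}"
                )
            s = math.fsum(row)
            if abs(s - 1.0) > ROW_SUM_TOL:
                raise NormalizationError(
                    f"CPT for {self.node!r} row {key}: sums to {s!r}, not 1"
                )


@dataclass(frozen=True)
class BnModel:
    """A validated discrete Bayesian network.

    The joint distribution is the chain-rule product of the per-node table
    rows.  ``bn_type`` records which uncertainty the probabilities express
    (epistemic / aleatory / predictive); ``provenance`` records how the
    tables were informed (expert judgment, data, or both).
    """

    nodes: tuple[NodeSpec, ...]
    cpts: Mapping[str, Cpt]
    bn_type: str = "aleatory"
    provenance: str = ""

    @property
    def node_map(self) -> dict[str, NodeSpec]:
        return {n.name: n for n in self.nodes}

    def node(self, name: str) -> NodeSpec:
        try:
            return self.node_map[name]
        except KeyError:
            raise InputError(f"unknown node {name!r}") from None

    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)


@dataclass(frozen=True)
class ClassificationAnswers:
    """Answers to the six uncertainty-classification criteria.

    Three criteria come straight from the published classification scheme
    (unique vs sampling event, certain vs uncertain quantities, informed by
    expert / data / both); the remaining three flags are reconstructed from
    the discussion of predictive networks (see docs/methods.md) and cover
    whether parameters are treated as known, whether case learning happened
    inside the network, and whether parameter uncertainty has been
    marginalized into the variables.
    """

    models_unique_event: bool
    quantities_uncertain: bool
    informed_by: str  # expert | data | both
    parameters_known: bool
    case_learning_inside: bool
    parameters_marginalized_into_variables: bool

    def __post_init__(self) -> None:
        if self.informed_by not in ("expert", "data", "both"):
            raise InputError(
                f"informed_by must be expert|data|both, got {self.informed_by!r}"
            )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def build_network(
    nodes: Sequence[NodeSpec],
    cpts: Iterable[Cpt],
    bn_type: str = "aleatory",
    provenance: str = "",
) -> BnModel:
    """Validate structure and tables and assemble a :class:`BnModel`.

    Raises
    ------
    StructuralError
        if the parent graph contains a cycle (the cycle is named) or a
        parent refers to an undeclared node.
    SchemaError
        if a node lacks a CPT, a CPT has missing/extra rows, or row keys do
        not enumerate the full parent-state product.
    NormalizationError
        if any row fails to sum to 1 within ``1e-9``.
    """
    nodes = tuple(nodes)
    if bn_type not in BN_TYPES:
        raise SchemaError(f"bn_type must be one of {BN_TYPES}, got {bn_type!r}")
    node_map = {n.name: n for n in nodes}
    if len(node_map) != len(nodes):
        raise SchemaError("duplicate node names")
    for n in nodes:
        for p in n.parents:
            if p not in node_map:
                raise StructuralError(f"node {n.name!r} has undeclared parent {p!r}")

    g = nx.DiGraph()
    g.add_nodes_from(node_map)
    for n in nodes:
        for p in n.parents:
            g.add_edge(p, n.name)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        pass
    else:
        members = tuple(dict.fromkeys(u for u, _ in cycle))
        raise StructuralError(f"cycle detected: {members}")

    cpt_map = {c.node: c for c in cpts}
    if set(cpt_map) != set(node_map):
        missing = sorted(set(node_map) - set(cpt_map))
        extra = sorted(set(cpt_map) - set(node_map))
        raise SchemaError(f"CPT set mismatch: missing {missing}, extra {extra}")
    for name, spec in node_map.items():
        cpt_map[name].validate(spec, node_map)

    return BnModel(nodes=nodes, cpts=cpt_map, bn_type=bn_type, provenance=provenance)


def renormalize_cpt(cpt: Cpt) -> Cpt:
    """Explicitly rescale every row to sum to 1 (never done silently)."""
    rows = {}
    for key, row in cpt.rows.items():
        s = math.fsum(row)
        if s <= 0:
            raise NormalizationError(f"CPT for {cpt.node!r} row {key}: nonpositive mass {s}")
        rows[key] = tuple(p / s for p in row)
    return Cpt(node=cpt.node, rows=rows)


def joint_probability(model: BnModel, assignment: Mapping[str, str]) -> float:
    """Chain-rule joint probability of one full assignment of states.

    ``P(x_1, ..., x_n) = prod_i P(x_i | parents(x_i))`` with each factor
    looked up directly in the node's table.
    """
    prob = 1.0
    node_map = model.node_map
    for spec in model.nodes:
        if spec.name not in assignment:
            raise InputError(f"assignment misses node {spec.name!r}")
        state = assignment[spec.name]
        if state not in spec.states:
            raise InputError(f"node {spec.name!r} has no state {state!r}")
        key = tuple(assignment[p] for p in spec.parents)
        row = model.cpts[spec.name].rows[key]
        prob *= row[spec.states.index(state)]
        if prob == 0.0:
            return 0.0
    return prob


def classify_network(answers: ClassificationAnswers) -> tuple[str, str]:
    """Classify a network as epistemic, aleatory, or predictive.

    The mapping is total and deterministic: every combination of answers
    yields a tag, and combinations the underlying scheme treats as
    contradictory are mapped with a warning embedded in the rationale.

    Returns
    -------
    (tag, rationale) : tuple of str
        ``tag`` is one of ``epistemic | aleatory | predictive``; the
        rationale cites which answers drove the outcome.
    """
    reasons: list[str] = []
    warnings: list[str] = []

    if answers.parameters_marginalized_into_variables:
        tag = "predictive"
        reasons.append(
            "parameter uncertainty has been marginalized into the variables, so the "
            "node probabilities are predictive distributions mixing aleatory and "
            "epistemic uncertainty in an unknown proportion"
        )
        if answers.models_unique_event:
            warnings.append(
                "a unique-event model with marginalized parameters is unusual; the "
                "predictive reading of the tables takes precedence"
            )
    elif answers.models_unique_event:
        tag = "epistemic"
        reasons.append(
            "the network models a unique event, so node probabilities are subjective "
            "degrees of belief (a genuine Bayesian belief network)"
        )
        if not answers.quantities_uncertain:
            warnings.append(
                "a unique-event network over quantities declared certain is "
                "contradictory; probabilistic reasoning presumes uncertain quantities"
            )
        if answers.informed_by in ("expert", "both"):
            reasons.append("tables are expert-informed, consistent with probabilistic reasoning")
    else:
        tag = "aleatory"
        reasons.append(
            "the network models a sampling event with table probabilities as best "
            "estimates of relative frequencies"
        )
        if answers.case_learning_inside:
            reasons.append(
                "case learning inside the network yields posterior probabilities used "
                "as best estimates, which keeps the network aleatory"
            )
        if not answers.parameters_known and not answers.case_learning_inside:
            warnings.append(
                "table probabilities are not treated as known and no in-network "
                "learning was done: parameter uncertainty must be treated outside "
                "the network (enhanced model, credal bounds, or scenarios)"
            )

    rationale = "; ".join(reasons)
    if warnings:
        rationale += ". WARNING: " + "; ".join(warnings)
    return tag, rationale


def full_assignments(model: BnModel) -> Iterable[dict[str, str]]:
    """Iterate over every full joint assignment (Cartesian state product)."""
    names = model.node_names()
    for combo in itertools.product(*(model.node(n).states for n in names)):
        yield dict(zip(names, combo))
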