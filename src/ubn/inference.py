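"""Exact query answering on discrete Bayesian networks.

Two independent routes compute ``P(target in event_states | evidence)``:

* :func:`eliminate_query` — variable elimination over table factors, the
  production path;
* :func:`enumerate_query` — brute-force summation over every full joint
  assignment, kept as a transparent oracle for testing and small models.

Evidence follows the standard two-tier scheme: *hard* evidence instantiates
a node to one state; *virtual* (likelihood) evidence multiplies the node's
factor by a non-negative weight vector — hard evidence is exactly the
special case of a one-hot weight vector.  Conditioning on an event of zero
probability raises :class:`~ubn.bn_core.InconsistentEvidenceError` rather
than returning 0/0: in risk assessment a null conditioning event signals a
modeling fault that must surface.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .bn_core import (
    BnModel,
    InconsistentEvidenceError,
    InputError,
    joint_probability,
)

ENUMERATION_LIMIT = 10**6


@dataclass(frozen=True)
class Evidence:
    """Evidence on one node: hard (a state label) or virtual (a likelihood
    vector over the node's states, at least one entry positive)."""

    node: str
    kind: str  # hard | virtual
    value: object  # str for hard, sequence of floats for virtual

    def __post_init__(self) -> None:
        if self.kind not in ("hard", "virtual"):
            raise InputError(f"evidence kind must be hard|virtual, got {self.kind!r}")
        if self.kind == "virtual":
            vec = tuple(float(w) for w in self.value)  # type: ignore[arg-type]
            if any(w < 0 for w in vec):
                raise InputError(f"virtual evidence on {self.node!r}: negative weight")
            if not any(w > 0 for w in vec):
                raise InputError(f"virtual evidence on {self.node!r}: all weights zero")
            object.__setattr__(self, "value", vec)

    @staticmethod
    def hard(node: str, state: str) -> "Evidence":
        return Evidence(node=node, kind="hard", value=state)

    @staticmethod
    def virtual(node: str, weights: Sequence[float]) -> "Evidence":
        return Evidence(node=node, kind="virtual", value=tuple(weights))


@dataclass(frozen=True)
class Query:
    """A conditional event query: P(target in event_states | evidence)."""

    target: str
    event_states: tuple[str, ...]
    evidence: tuple[Evidence, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "event_states", tuple(self.event_states))
        object.__setattr__(self, "evidence", tuple(self.evidence))
        if not self.event_states:
            raise InputError("event_states must be non-empty")
        seen = [e.node for e in self.evidence]
        if len(seen) != len(set(seen)):
            raise InputError("at most one evidence item per node")

    def describe(self) -> str:
        if self.name:
            return self.name
        ev = ", ".join(
            f"{e.node}={e.value}" if e.kind == "hard" else f"{e.node}~{list(e.value)}"
            for e in self.evidence
        )
        body = f"P({self.target} in {{{', '.join(self.event_states)}}}"
        return body + (f" | {ev})" if ev else ")")


# ---------------------------------------------------------------------------
# Factors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Factor:
    vars: tuple[str, ...]
    table: np.ndarray  # shape = state cardinalities of vars, in order

    def multiply(self, other: "_Factor") -> "_Factor":
        all_vars = self.vars + tuple(v for v in other.vars if v not in self.vars)
        a = _broadcast(self, all_vars)
        b = _broadcast(other, all_vars)
        return _Factor(vars=all_vars, table=a * b)

    def sum_out(self, var: str) -> "_Factor":
        axis = self.vars.index(var)
        return _Factor(
            vars=self.vars[:axis] + self.vars[axis + 1 :],
            table=self.table.sum(axis=axis),
        )


def _broadcast(f: _Factor, all_vars: tuple[str, ...]) -> np.ndarray:
    # align f.table onto the all_vars axis order, adding singleton axes
    perm = [f.vars.index(v) for v in all_vars if v in f.vars]
    t = np.transpose(f.table, perm) if perm else f.table
    shape = [t.shape[[v for v in all_vars if v in f.vars].index(v)] if v in f.vars else 1
             for v in all_vars]
    return t.reshape(shape)


def _model_factors(model: BnModel) -> list[_Factor]:
    factors = []
    for spec in model.nodes:
        dims = tuple(model.node(p).states for p in spec.parents) + (spec.states,)
        fvars = spec.parents + (spec.name,)
        shape = tuple(len(d) for d in dims)
        table = np.empty(shape)
        cpt = model.cpts[spec.name]
        if spec.parents:
            for idx in itertools.product(*(range(len(d)) for d in dims[:-1])):
                key = tuple(model.node(p).states[i] for p, i in zip(spec.parents, idx))
                table[idx] = cpt.rows[key]
        else:
            table[:] = cpt.rows[()]
        factors.append(_Factor(vars=fvars, table=table))
    return factors


def _evidence_vector(model: BnModel, e: Evidence) -> np.ndarray:
    spec = model.node(e.node)
    if e.kind == "hard":
        if e.value not in spec.states:
            raise InputError(f"node {e.node!r} has no state {e.value!r}")
        vec = np.zeros(len(spec.states))
        vec[spec.states.index(e.value)] = 1.0
        return vec
    vec = np.asarray(e.value, dtype=float)
    if vec.shape != (len(spec.states),):
        raise InputError(
            f"virtual evidence on {e.node!r}: {vec.size} weights for "
            f"{len(spec.states)} states"
        )
    return vec


def _indicator_vector(model: BnModel, node: str, states: Sequence[str]) -> np.ndarray:
    spec = model.node(node)
    vec = np.zeros(len(spec.states))
    for s in states:
        if s not in spec.states:
            raise InputError(f"node {node!r} has no state {s!r}")
        vec[spec.states.index(s)] = 1.0
    return vec


def _eliminate_all(model: BnModel, factors: list[_Factor]) -> float:
    """Sum out every variable; min-degree ordering, lexicographic ties."""
    remaining = set()
    for f in factors:
        remaining.update(f.vars)
    factors = list(factors)
    while remaining:
        # degree = number of distinct neighbours in the factor graph
        degree = {}
        for v in remaining:
            neigh = set()
            for f in factors:
                if v in f.vars:
                    neigh.update(f.vars)
            neigh.discard(v)
            degree[v] = len(neigh)
        var = min(remaining, key=lambda v: (degree[v], v))
        touching = [f for f in factors if var in f.vars]
        rest = [f for f in factors if var not in f.vars]
        prod = touching[0]
        for f in touching[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.sum_out(var)]
        remaining.discard(var)
    result = 1.0
    for f in factors:
        result *= float(f.table)  # all scalars now
    return result


def _posterior_event_probability(
    model: BnModel,
    event: Mapping[str, Sequence[str]],
    evidence: Sequence[Evidence],
) -> float:
    """P(conjunction event | evidence) by two eliminations (joint / norm)."""
    base = _model_factors(model)
    ev_factors = [
        _Factor(vars=(e.node,), table=_evidence_vector(model, e)) for e in evidence
    ]
    ind_factors = [
        _Factor(vars=(node,), table=_indicator_vector(model, node, states))
        for node, states in event.items()
    ]
    denom = _eliminate_all(model, base + ev_factors)
    if denom <= 0.0:
        raise InconsistentEvidenceError(
            "evidence has zero probability under the model: "
            + ", ".join(f"{e.node}" for e in evidence)
        )
    numer = _eliminate_all(model, base + ev_factors + ind_factors)
    # guard fp noise: the ratio is a probability by construction
    return min(max(numer / denom, 0.0), 1.0)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def eliminate_query(model: BnModel, query: Query) -> float:
    """P(target in event_states | evidence) by variable elimination."""
    model.node(query.target)  # validates target exists
    return _posterior_event_probability(
        model, {query.target: query.event_states}, query.evidence
    )


def event_probability(
    model: BnModel,
    event: Mapping[str, Sequence[str]],
    evidence: Sequence[Evidence] = (),
) -> float:
    """Probability of a conjunction event over several nodes given evidence.

    The event maps each participating node to an allowed subset of its
    states; the result is P(AND_n target_n in subset_n | evidence), computed
    exactly by elimination with one indicator factor per event node.
    """
    if not event:
        raise InputError("event must name at least one node")
    return _posterior_event_probability(model, event, evidence)


def enumerate_query(model: BnModel, query: Query) -> float:
    """Brute-force oracle: sum joint x likelihood weights over all
    assignments.  Refuses state spaces above 10^6 configurations."""
    size = 1
    for n in model.nodes:
        size *= len(n.states)
        if size > ENUMERATION_LIMIT:
            raise InputError(
                f"state space exceeds enumeration limit ({ENUMERATION_LIMIT}); "
                "use eliminate_query"
            )
    model.node(query.target)
    weights = {e.node: _evidence_vector(model, e) for e in query.evidence}
    numer = 0.0
    denom = 0.0
    names = model.node_names()
    state_lists = [model.node(n).states for n in names]
    for combo in itertools.product(*state_lists):
        assignment = dict(zip(names, combo))
        w = joint_probability(model, assignment)
        for node, vec in weights.items():
            w *= vec[model.node(node).states.index(assignment[node])]
        denom += w
        if assignment[query.target] in query.event_states:
            numer += w
    if denom <= 0.0:
        raise InconsistentEvidenceError(
            "evidence has zero probability under the model"
        )
    return numer / denom
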