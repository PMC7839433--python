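"""Structural uncertainty via ensembles of Bayesian networks.

A single network cannot express uncertainty about its own structure.  This
module treats structural uncertainty with a set of alternative models that
share the query target:

* :func:`average_query` — Bayesian model averaging of the query result
  under weights over the members (expert-assigned or likelihood-derived);
* :func:`likelihood_weights` — weights proportional to prior times the
  marginal likelihood of shared observed cases under each member;
* :func:`scenario_query` — uncertainty scenarios: per-member answers kept
  separate, never integrated, reported with their range;
* :func:`robust_scan` — minimax screening of management alternatives: rank
  decisions by their worst-case adverse-event probability across scenarios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bn_core import BnModel, InputError, SchemaError, UbnError
from .inference import (
    Evidence,
    InconsistentEvidenceError,
    Query,
    eliminate_query,
    event_probability,
)


class WeightError(UbnError):
    """Weights are missing, malformed, or degenerate to all-zero."""


@dataclass(frozen=True)
class ModelSet:
    """Labelled alternative models sharing the query target.

    Members may differ in nodes, links, and discretization, but every
    member must declare the target node with identical states so the same
    question can be asked of each.  ``weights`` (optional) is a probability
    vector over members for model averaging.
    """

    members: tuple[tuple[str, BnModel], ...]
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        members = tuple((str(l), m) for l, m in self.members)
        object.__setattr__(self, "members", members)
        if not members:
            raise SchemaError("ModelSet needs at least one member")
        labels = [l for l, _ in members]
        if len(set(labels)) != len(labels):
            raise SchemaError("member labels must be unique")
        if self.weights is not None:
            w = tuple(float(x) for x in self.weights)
            object.__setattr__(self, "weights", w)
            if len(w) != len(members):
                raise SchemaError("one weight per member required")
            if any(x < 0 for x in w) or abs(math.fsum(w) - 1.0) > 1e-9:
                raise SchemaError("weights must be a probability vector summing to 1")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(l for l, _ in self.members)

    def require_shared_target(self, target: str) -> None:
        specs = []
        for label, m in self.members:
            if target not in m.node_map:
                raise InputError(f"member {label!r} lacks target node {target!r}")
            specs.append(m.node(target).states)
        if len(set(specs)) != 1:
            raise SchemaError(f"members disagree on the states of target {target!r}")


@dataclass(frozen=True)
class ScenarioResult:
    """Per-scenario query answers, never aggregated."""

    results: Mapping[str, float]

    @property
    def range(self) -> tuple[float, float]:
        vals = list(self.results.values())
        return (min(vals), max(vals))


def _check_evidence_nodes(ms: ModelSet, query: Query) -> None:
    # evidence naming a node absent from any member is an error, never a skip:
    # silently dropping evidence changes the question per member
    for e in query.evidence:
        for label, m in ms.members:
            if e.node not in m.node_map:
                raise InputError(
                    f"evidence node {e.node!r} absent from member {label!r}"
                )


def average_query(ms: ModelSet, query: Query) -> float:
    """Model-averaged query probability: sum_m w_m P_m(event | evidence)."""
    if ms.weights is None:
        raise WeightError(
            "ModelSet has no weights; use scenario_query for unweighted "
            "scenarios or derive weights with likelihood_weights first"
        )
    ms.require_shared_target(query.target)
    _check_evidence_nodes(ms, query)
    return float(
        sum(w * eliminate_query(m, query) for w, (_, m) in zip(ms.weights, ms.members))
    )


def likelihood_weights(
    ms: ModelSet,
    cases: pd.DataFrame,
    prior_weights: Sequence[float] | None = None,
) -> tuple[float, ...]:
    """Posterior model weights from shared observed cases.

    ``w_m proportional to prior_m * prod_cases P_m(case)`` with each case's
    probability computed per member by marginalizing over that member's
    unobserved nodes; accumulated in log space.  Case columns must be nodes
    present in every member (the shared observable subset).  A member
    assigning zero probability to any case gets weight 0 with a warning;
    all members at zero is an error.
    """
    n = len(ms.members)
    prior = np.full(n, 1.0 / n) if prior_weights is None else np.asarray(prior_weights, float)
    if prior.shape != (n,) or (prior < 0).any() or abs(prior.sum() - 1.0) > 1e-9:
        raise WeightError("prior weights must be a probability vector over members")
    for col in cases.columns:
        for label, m in ms.members:
            if col not in m.node_map:
                raise InputError(
                    f"case column {col!r} is not a node of member {label!r}; "
                    "cases must use the shared observable subset"
                )
    loglik = np.zeros(n)
    dead = np.zeros(n, dtype=bool)
    for _, case in cases.iterrows():
        for i, (label, m) in enumerate(ms.members):
            if dead[i]:
                continue
            event = {col: (str(case[col]),) for col in cases.columns}
            p = event_probability(m, event)
            if p <= 0.0:
                dead[i] = True
                warnings.warn(
                    f"member {label!r} assigns zero probability to an observed "
                    "case; its weight is 0"
                )
            else:
                loglik[i] += math.log(p)
    if dead.all() or (prior[~dead] == 0).all():
        raise WeightError("every member assigns zero probability to the cases")
    log_post = np.where(dead | (prior == 0), -np.inf, np.log(np.where(prior > 0, prior, 1.0)) + loglik)
    log_post -= log_post[np.isfinite(log_post)].max()
    w = np.where(np.isfinite(log_post), np.exp(log_post), 0.0)
    return tuple(w / w.sum())


def scenario_query(ms: ModelSet, query: Query) -> ScenarioResult:
    """Answer the query separately in every scenario member, no aggregation."""
    ms.require_shared_target(query.target)
    _check_evidence_nodes(ms, query)
    return ScenarioResult(
        results={label: eliminate_query(m, query) for label, m in ms.members}
    )


@dataclass(frozen=True)
class RobustScanResult:
    """Minimax ranking of decisions across scenario models.

    ``matrix`` maps (decision label, scenario label) to the adverse-event
    probability; flagged cells hold None (inconsistent evidence), and the
    decision is excluded from ``ranking``.
    """

    matrix: Mapping[tuple[str, str], float | None]
    worst_case: Mapping[str, float]
    ranking: tuple[str, ...]
    excluded: tuple[str, ...]


def robust_scan(
    ms: ModelSet,
    decisions: Sequence[tuple[str, Sequence[Evidence]]],
    query: Query,
) -> RobustScanResult:
    """Rank management alternatives by worst-case adverse probability.

    Each decision is an evidence set applied (on top of the query's own
    evidence) to every scenario member; the query is an adverse-event
    probability, lower is better.  Decisions are ranked ascending by their
    maximum probability across scenarios (minimax); a decision whose
    evidence is inconsistent in some scenario is flagged and excluded.
    """
    ms.require_shared_target(query.target)
    labels = [d for d, _ in decisions]
    if len(set(labels)) != len(labels):
        raise InputError("decision labels must be unique")
    matrix: dict[tuple[str, str], float | None] = {}
    worst: dict[str, float] = {}
    excluded: list[str] = []
    query_ev_nodes = {e.node for e in query.evidence}
    for dlabel, ev in decisions:
        ev = tuple(ev)
        overlap = query_ev_nodes & {e.node for e in ev}
        if overlap:
            raise InputError(
                f"decision {dlabel!r} re-instantiates query evidence nodes {sorted(overlap)}"
            )
        combined = query.evidence + ev
        for e in combined:
            for slabel, m in ms.members:
                if e.node not in m.node_map:
                    raise InputError(
                        f"evidence node {e.node!r} absent from scenario {slabel!r}"
                    )
        ok = True
        vals = []
        for slabel, m in ms.members:
            q = Query(target=query.target, event_states=query.event_states,
                      evidence=combined, name=query.name)
            try:
                p = eliminate_query(m, q)
            except InconsistentEvidenceError:
                matrix[(dlabel, slabel)] = None
                ok = False
                continue
            matrix[(dlabel, slabel)] = p
            vals.append(p)
        if ok:
            worst[dlabel] = max(vals)
        else:
            excluded.append(dlabel)
            warnings.warn(
                f"decision {dlabel!r} excluded: evidence inconsistent in some scenario"
            )
    ranking = tuple(sorted(worst, key=lambda d: (worst[d], d)))
    return RobustScanResult(
        matrix=matrix, worst_case=worst, ranking=ranking, excluded=tuple(excluded)
    )
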