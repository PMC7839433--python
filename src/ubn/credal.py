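"""Credal (interval-probability) networks and the imprecise Dirichlet model.

A credal network replaces each node-state probability with a closed
interval, turning every table row into a *separately specified interval
credal set*: the set of probability vectors with each coordinate inside its
interval and coordinates summing to 1.  Queries then yield lower and upper
probabilities instead of a point value.

Bounds are computed either exactly, by enumerating the extreme points
(vertices) of every row's credal set and taking the min/max of the exact
conditional query over all vertex combinations, or approximately from the
inside, by sampling valid tables within the intervals (an optimistic inner
bound, always contained in the vertex bounds).

The imprecise Dirichlet model (IDM) turns state counts into intervals:
``lower_k = n_k / (N + s)``, ``upper_k = (n_k + s) / (N + s)`` — vacuous
before any data and shrinking toward the relative frequencies as N grows.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .bn_core import (
    BnModel,
    Cpt,
    InputError,
    NodeSpec,
    SchemaError,
    UbnError,
)
from .inference import InconsistentEvidenceError, Query, eliminate_query
from .param_uncertainty import EnhancedBn

IDM_DEFAULT_S = 2.0
VERTEX_COMBINATION_LIMIT = 10**6
MAX_STATES_FOR_VERTEX = 5


class BudgetError(UbnError):
    """Vertex-combination budget exceeded; use inner sampling instead."""


@dataclass(frozen=True)
class CredalRow:
    """Closed probability intervals per state for one table row.

    The credal set is non-empty iff ``sum(lower) <= 1 <= sum(upper)`` with
    ``0 <= lower_k <= upper_k <= 1``; the row is degenerate (a point) when
    lower equals upper.
    """

    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        lo = tuple(float(x) for x in self.lower)
        up = tuple(float(x) for x in self.upper)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)
        if len(lo) != len(up):
            raise SchemaError("lower/upper length mismatch")
        tol = 1e-12
        for k, (a, b) in enumerate(zip(lo, up)):
            if not (-tol <= a <= b <= 1 + tol):
                raise SchemaError(
                    f"state {k}: need 0 <= lower <= upper <= 1, got [{a}, {b}]"
                )
        if math.fsum(lo) > 1 + 1e-9 or math.fsum(up) < 1 - 1e-9:
            raise SchemaError(
                f"empty credal set: sum(lower)={math.fsum(lo)!r}, "
                f"sum(upper)={math.fsum(up)!r} must bracket 1"
            )

    @property
    def is_degenerate(self) -> bool:
        return all(abs(a - b) <= 1e-12 for a, b in zip(self.lower, self.upper))

    def vertices(self) -> list[tuple[float, ...]]:
        """Extreme points of the interval credal set.

        Greedy construction: for each permutation of states, walk the
        permutation assigning each state the largest value its upper bound
        and the remaining states' lower bounds allow; duplicates removed.
        Exact for separately specified interval credal sets.
        """
        k = len(self.lower)
        if self.is_degenerate:
            return [tuple(self.lower)]
        if k > MAX_STATES_FOR_VERTEX:
            raise BudgetError(
                f"vertex enumeration refused for rows with > {MAX_STATES_FOR_VERTEX} "
                f"states (got {k}); use inner sampling"
            )
        out: dict[tuple[float, ...], None] = {}
        for perm in itertools.permutations(range(k)):
            p = [0.0] * k
            assigned = 0.0
            remaining_lower = math.fsum(self.lower)
            for idx in perm:
                remaining_lower -= self.lower[idx]
                budget = 1.0 - assigned - remaining_lower
                p[idx] = min(self.upper[idx], max(self.lower[idx], budget))
                assigned += p[idx]
            if abs(assigned - 1.0) <= 1e-9:
                out[tuple(round(v, 15) for v in p)] = None
        return list(out)


@dataclass(frozen=True)
class CredalBn:
    """A credal network: BN structure plus one CredalRow per table row.

    ``flavor`` records whether the intervals bound relative frequencies
    (``aleatory_credal``) or widen subjective probabilities to express
    indirect uncertainty (``epistemic_credal``); the distinction is
    interpretive metadata, not computational.
    """

    nodes: tuple[NodeSpec, ...]
    credal_cpts: Mapping[str, Mapping[tuple[str, ...], CredalRow]]
    flavor: str = "aleatory_credal"

    def __post_init__(self) -> None:
        if self.flavor not in ("aleatory_credal", "epistemic_credal"):
            raise SchemaError(f"unknown credal flavor {self.flavor!r}")
        node_map = {n.name: n for n in self.nodes}
        if set(self.credal_cpts) != set(node_map):
            raise SchemaError("credal CPT set must match node set")
        for name, rows in self.credal_cpts.items():
            spec = node_map[name]
            expected = (
                set(itertools.product(*(node_map[p].states for p in spec.parents)))
                if spec.parents
                else {()}
            )
            if set(rows) != expected:
                raise SchemaError(f"credal rows for {name!r} do not enumerate parent configs")
            for key, row in rows.items():
                if len(row.lower) != len(spec.states):
                    raise SchemaError(
                        f"credal row for {name!r}{key}: wrong number of states"
                    )

    @property
    def node_map(self) -> dict[str, NodeSpec]:
        return {n.name: n for n in self.nodes}


@dataclass(frozen=True)
class BoundsResult:
    """Lower/upper probability bounds on a query.

    ``method`` is ``vertex_enumeration`` (exact for interval credal sets)
    or ``inner_sampling`` (an optimistic inner approximation, flagged).
    """

    lower: float
    upper: float
    method: str
    evaluations: int

    def __post_init__(self) -> None:
        if self.lower > self.upper + 1e-12:
            raise SchemaError(f"lower {self.lower} > upper {self.upper}")

    @property
    def is_inner_approximation(self) -> bool:
        return self.method == "inner_sampling"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def idm_intervals(counts: Sequence[float], s: float = IDM_DEFAULT_S) -> CredalRow:
    """Imprecise-Dirichlet-model intervals from state counts.

    ``lower_k = n_k/(N+s)``, ``upper_k = (n_k+s)/(N+s)`` with N the count
    total; vacuous ([0,1] everywhere) at N = 0 and shrinking toward the
    relative frequencies with width ``s/(N+s)`` as N grows.
    """
    if s <= 0:
        raise InputError(f"IDM hyperparameter s must be > 0, got {s}")
    n = np.asarray(counts, dtype=float)
    if (n < 0).any():
        raise InputError("counts must be non-negative")
    total = n.sum()
    lower = n / (total + s)
    upper = (n + s) / (total + s)
    return CredalRow(lower=tuple(lower), upper=tuple(upper))


def from_enhanced(enhanced: EnhancedBn, level: float = 0.95) -> CredalBn:
    """Turn Dirichlet rows into interval rows via central credible intervals.

    Each state's marginal under a Dirichlet row is Beta(alpha_k, s-alpha_k);
    the interval is its equal-tailed credible interval at ``level``.
    Sentinel rows map to degenerate (point) intervals.  The result is
    flagged ``epistemic_credal``: bounds widening a subjective probability.
    """
    if not 0 < level < 1:
        raise InputError(f"level must be in (0, 1), got {level}")
    q_lo, q_hi = (1 - level) / 2, 1 - (1 - level) / 2
    credal_cpts: dict[str, dict[tuple[str, ...], CredalRow]] = {}
    for spec in enhanced.base.nodes:
        rows = {}
        for key, drow in enhanced.enhanced_cpts[spec.name].rows.items():
            if drow.is_sentinel:
                rows[key] = CredalRow(lower=drow.mean, upper=drow.mean)
                continue
            alpha = np.asarray(drow.concentration)
            s_total = alpha.sum()
            lower, upper = [], []
            for a in alpha:
                b = s_total - a
                lower.append(float(stats.beta.ppf(q_lo, a, b)))
                upper.append(float(stats.beta.ppf(q_hi, a, b)))
            rows[key] = CredalRow(lower=tuple(lower), upper=tuple(upper))
        credal_cpts[spec.name] = rows
    return CredalBn(
        nodes=enhanced.base.nodes, credal_cpts=credal_cpts, flavor="epistemic_credal"
    )


def _as_model(credal: CredalBn, choice: Mapping[str, Mapping[tuple[str, ...], tuple[float, ...]]]) -> BnModel:
    cpts = {
        name: Cpt(node=name, rows=dict(rows)) for name, rows in choice.items()
    }
    return BnModel(nodes=credal.nodes, cpts=cpts, bn_type="aleatory",
                   provenance="credal vertex selection")


def _row_items(credal: CredalBn) -> list[tuple[str, tuple[str, ...], CredalRow]]:
    items = []
    for spec in credal.nodes:
        for key, row in credal.credal_cpts[spec.name].items():
            items.append((spec.name, key, row))
    return items


def bound_query(
    credal: CredalBn,
    query: Query,
    method: str = "vertex_enumeration",
    draws: int = 2000,
    seed: int = 0,
) -> BoundsResult:
    """Lower/upper probability of a query over the credal network.

    ``vertex_enumeration`` evaluates the exact conditional query at every
    combination of row vertices and takes the min/max — exact for
    separately specified interval credal sets, refused beyond 10^6
    combinations.  ``inner_sampling`` samples valid tables inside the
    intervals; its bounds are an inner approximation contained in the
    vertex bounds.  Vertex combinations under which the evidence is
    inconsistent are skipped (they do not constrain the conditional).
    """
    items = _row_items(credal)
    if method == "vertex_enumeration":
        vertex_lists = [row.vertices() for _, _, row in items]
        n_comb = 1
        for v in vertex_lists:
            n_comb *= len(v)
            if n_comb > VERTEX_COMBINATION_LIMIT:
                raise BudgetError(
                    f"vertex combinations exceed {VERTEX_COMBINATION_LIMIT}; "
                    "use method='inner_sampling'"
                )
        lo, hi = math.inf, -math.inf
        evaluations = 0
        for combo in itertools.product(*vertex_lists):
            choice: dict[str, dict[tuple[str, ...], tuple[float, ...]]] = {}
            for (name, key, _), vec in zip(items, combo):
                choice.setdefault(name, {})[key] = vec
            model = _as_model(credal, choice)
            try:
                p = eliminate_query(model, query)
            except InconsistentEvidenceError:
                continue
            evaluations += 1
            lo, hi = min(lo, p), max(hi, p)
        if evaluations == 0:
            raise InconsistentEvidenceError(
                "evidence inconsistent at every vertex combination"
            )
        return BoundsResult(lower=lo, upper=hi, method="vertex_enumeration",
                            evaluations=evaluations)

    if method == "inner_sampling":
        rng = np.random.default_rng(seed)
        lo, hi = math.inf, -math.inf
        evaluations = 0
        for _ in range(draws):
            choice: dict[str, dict[tuple[str, ...], tuple[float, ...]]] = {}
            for name, key, row in items:
                choice.setdefault(name, {})[key] = _sample_row(row, rng)
            model = _as_model(credal, choice)
            try:
                p = eliminate_query(model, query)
            except InconsistentEvidenceError:
                continue
            evaluations += 1
            lo, hi = min(lo, p), max(hi, p)
        if evaluations == 0:
            raise InconsistentEvidenceError(
                "evidence inconsistent in every sampled table"
            )
        return BoundsResult(lower=lo, upper=hi, method="inner_sampling",
                            evaluations=evaluations)

    raise InputError(f"unknown method {method!r}")


def _sample_row(row: CredalRow, rng: np.random.Generator, max_tries: int = 1000) -> tuple[float, ...]:
    """One valid table row inside the intervals.

    Uniform rejection on the simplex; rows too narrow for rejection fall
    back to a random convex combination of the row's vertices (still inside
    the credal set, preserving the inner-bound guarantee).
    """
    if row.is_degenerate:
        return tuple(row.lower)
    k = len(row.lower)
    lo = np.asarray(row.lower)
    up = np.asarray(row.upper)
    for _ in range(max_tries):
        p = rng.dirichlet(np.ones(k))
        if (p >= lo - 1e-12).all() and (p <= up + 1e-12).all():
            return tuple(np.clip(p, lo, up) / np.clip(p, lo, up).sum())
    verts = np.asarray(row.vertices())
    w = rng.dirichlet(np.ones(len(verts)))
    p = w @ verts
    return tuple(p / p.sum())
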