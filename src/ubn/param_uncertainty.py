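"""Enhanced Bayesian networks: Dirichlet uncertainty on table probabilities.

An *enhanced* BN is an aleatory BN whose table rows each carry a Dirichlet
parameter model: mean vector ``t``, equivalent sample size ``s``, and
concentration ``alpha = s * t``.  Rows are mutually independent across
parent configurations and across nodes (global parameter independence, the
standard Dirichlet-BN assumption).

This supports:

* conjugate case learning (``alpha' = alpha + n`` from complete cases);
* collapsing to an aleatory BN at the posterior-mean tables, or to a
  predictive BN (numerically the same tables for one next observation —
  the tag and provenance, not the numbers, carry the distinction);
* Monte-Carlo propagation of parameter uncertainty: sample one table draw
  per row, answer the query on each sampled network, and summarize the
  resulting distribution over the query probability.

A row may be a point mass (no parameter uncertainty) via the explicit
``s = inf`` sentinel; sentinel rows sample to their mean exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bn_core import (
    BnModel,
    Cpt,
    InputError,
    NormalizationError,
    SchemaError,
    UbnError,
)
from .inference import InconsistentEvidenceError, Query, eliminate_query

SENTINEL = math.inf  # explicit "no parameter uncertainty" flag for s

#: Fraction of inconsistent-evidence draws tolerated during propagation
#: before the run is treated as a model fault.
MAX_DROPPED_FRACTION = 0.01


class PropagationError(UbnError):
    """Monte-Carlo propagation failed (e.g. evidence inconsistent in too
    many sampled networks)."""


@dataclass(frozen=True)
class DirichletRow:
    """Dirichlet model for one table row: mean t, equivalent sample size s.

    The concentration is ``alpha_k = s * t_k``; ``s = inf`` marks a point
    mass at the mean (no epistemic uncertainty about this row).
    """

    mean: tuple[float, ...]
    equivalent_sample_size: float

    def __post_init__(self) -> None:
        mean = tuple(float(p) for p in self.mean)
        object.__setattr__(self, "mean", mean)
        s = float(self.equivalent_sample_size)
        object.__setattr__(self, "equivalent_sample_size", s)
        if abs(math.fsum(mean) - 1.0) > 1e-9:
            raise NormalizationError(f"DirichletRow mean sums to {math.fsum(mean)!r}")
        if any(p < 0 for p in mean):
            raise NormalizationError("DirichletRow mean has negative entries")
        if s <= 0:
            raise InputError(f"equivalent sample size must be > 0, got {s}")
        if not self.is_sentinel and any(p == 0.0 for p in mean):
            raise InputError(
                "zero mean entry with finite s gives a zero Dirichlet "
                "concentration; use the s = inf sentinel or assign explicit "
                "positive mass"
            )
        if not self.is_sentinel:
            # cache alpha so conjugate updates stay exact in alpha space
            object.__setattr__(self, "_alpha", tuple(s * t for t in mean))

    @classmethod
    def from_concentration(
        cls, alpha: Sequence[float], s: float | None = None
    ) -> "DirichletRow":
        """Build a row from exact concentrations (alpha kept bit-faithful).

        ``s`` may be supplied when a more exact total than ``sum(alpha)``
        is known (e.g. prior size + integer case count); it must agree with
        the concentration total to 1e-9.
        """
        alpha = tuple(float(a) for a in alpha)
        if any(a <= 0 for a in alpha):
            raise InputError("Dirichlet concentrations must be positive")
        total = math.fsum(alpha)
        if s is None:
            s = total
        elif abs(s - total) > 1e-9 * max(1.0, abs(s)):
            raise InputError(f"s={s} disagrees with sum(alpha)={total}")
        row = cls(mean=tuple(a / s for a in alpha), equivalent_sample_size=float(s))
        object.__setattr__(row, "_alpha", alpha)
        return row

    @property
    def is_sentinel(self) -> bool:
        return math.isinf(self.equivalent_sample_size)

    @property
    def concentration(self) -> tuple[float, ...]:
        if self.is_sentinel:
            raise InputError("sentinel row has no finite concentration")
        return self._alpha  # type: ignore[attr-defined]


@dataclass(frozen=True)
class EnhancedCpt:
    """Per parent-configuration Dirichlet rows for one node; rows are
    mutually independent."""

    node: str
    rows: Mapping[tuple[str, ...], DirichletRow]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", {tuple(k): v for k, v in self.rows.items()})


@dataclass(frozen=True)
class EnhancedBn:
    """An aleatory BN expanded with Dirichlet models over its table rows."""

    base: BnModel
    enhanced_cpts: Mapping[str, EnhancedCpt]

    def __post_init__(self) -> None:
        if self.base.bn_type != "aleatory":
            raise SchemaError(
                f"enhanced networks wrap aleatory BNs, got bn_type={self.base.bn_type!r}"
            )
        if set(self.enhanced_cpts) != set(self.base.node_map):
            raise SchemaError("enhanced CPT set must match the node set")
        for name, ecpt in self.enhanced_cpts.items():
            base_rows = set(self.base.cpts[name].rows)
            if set(ecpt.rows) != base_rows:
                raise SchemaError(f"enhanced rows for {name!r} do not match base CPT rows")


@dataclass(frozen=True)
class QueryUncertainty:
    """Sample-based distribution over a query probability."""

    samples: tuple[float, ...]
    draw_count: int
    seed: int
    query: Query
    dropped: int = 0

    def __post_init__(self) -> None:
        samples = tuple(float(x) for x in self.samples)
        object.__setattr__(self, "samples", samples)
        if any(x < 0 or x > 1 for x in samples):
            raise InputError("query-probability samples must lie in [0, 1]")
        if self.draw_count != len(samples):
            raise InputError("draw_count must equal the number of samples")


# ---------------------------------------------------------------------------
# Construction and learning
# ---------------------------------------------------------------------------


def make_enhanced(cpt: Cpt, s: float | Mapping[tuple[str, ...], float]) -> EnhancedCpt:
    """Attach Dirichlet models to a CPT: per row, ``alpha = s * t``.

    ``s`` may be a single equivalent sample size for all rows or a mapping
    from row key to size; ``inf`` marks a point-mass (sentinel) row.
    """
    rows = {}
    for key, t in cpt.rows.items():
        s_row = float(s[key]) if isinstance(s, Mapping) else float(s)
        rows[key] = DirichletRow(mean=t, equivalent_sample_size=s_row)
    return EnhancedCpt(node=cpt.node, rows=rows)


def make_enhanced_bn(
    model: BnModel, s: float | Mapping[str, float | Mapping[tuple[str, ...], float]]
) -> EnhancedBn:
    """Wrap a whole aleatory BN; ``s`` is global, per-node, or per-row."""
    ecpts = {}
    for name, cpt in model.cpts.items():
        s_node = s[name] if isinstance(s, Mapping) else s
        ecpts[name] = make_enhanced(cpt, s_node)
    return EnhancedBn(base=model, enhanced_cpts=ecpts)


def update_from_cases(enhanced: EnhancedBn, cases: pd.DataFrame) -> EnhancedBn:
    """Conjugate Dirichlet-multinomial update from complete discrete cases.

    Per row, the posterior concentration is ``alpha' = alpha + n`` where
    ``n`` counts cases with that node state under that parent
    configuration; rows untouched by data are unchanged, and sentinel rows
    (infinite confidence) stay sentinel.
    """
    if cases.isna().any().any():
        raise InputError("cases contain missing values; only complete cases supported")
    model = enhanced.base
    for col in cases.columns:
        if col not in model.node_map:
            raise InputError(f"case column {col!r} is not a model node")
        valid = set(model.node(col).states)
        bad = set(cases[col].astype(str)) - valid
        if bad:
            raise InputError(f"column {col!r} has unknown state labels {sorted(bad)}")
    required = set(model.node_map)
    if set(cases.columns) != required:
        missing = sorted(required - set(cases.columns))
        raise InputError(f"cases must cover every node; missing columns {missing}")

    new_ecpts = {}
    for spec in model.nodes:
        ecpt = enhanced.enhanced_cpts[spec.name]
        rows = {}
        for key, drow in ecpt.rows.items():
            if drow.is_sentinel:
                rows[key] = drow
                continue
            mask = pd.Series(True, index=cases.index)
            for parent, pstate in zip(spec.parents, key):
                mask &= cases[parent].astype(str) == pstate
            sub = cases.loc[mask, spec.name].astype(str)
            counts = np.array([(sub == st).sum() for st in spec.states], dtype=float)
            alpha = np.asarray(drow.concentration) + counts
            s_new = drow.equivalent_sample_size + float(counts.sum())
            rows[key] = DirichletRow.from_concentration(alpha, s=s_new)
        new_ecpts[spec.name] = EnhancedCpt(node=spec.name, rows=rows)

    base = replace(
        model,
        provenance=(model.provenance + "; " if model.provenance else "")
        + f"updated from {len(cases)} complete cases (conjugate)",
    )
    return EnhancedBn(base=base, enhanced_cpts=new_ecpts)


# ---------------------------------------------------------------------------
# Sampling and collapsing
# ---------------------------------------------------------------------------


def sample_cpts(
    enhanced: EnhancedBn, seed: int | np.random.Generator
) -> BnModel:
    """Draw one aleatory BN: one independent Dirichlet draw per row.

    Sentinel rows return their mean exactly.  Deterministic under a fixed
    integer seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cpts = []
    for spec in enhanced.base.nodes:
        ecpt = enhanced.enhanced_cpts[spec.name]
        rows = {}
        for key, drow in ecpt.rows.items():
            if drow.is_sentinel:
                rows[key] = drow.mean
            else:
                draw = rng.dirichlet(drow.concentration)
                rows[key] = tuple(draw / draw.sum())
        cpts.append(Cpt(node=spec.name, rows=rows))
    return BnModel(
        nodes=enhanced.base.nodes,
        cpts={c.node: c for c in cpts},
        bn_type="aleatory",
        provenance="sampled table draw from enhanced model",
    )


def collapse_to_aleatory(enhanced: EnhancedBn) -> BnModel:
    """Set each row to its Dirichlet mean ``alpha / sum(alpha)``."""
    cpts = []
    for spec in enhanced.base.nodes:
        ecpt = enhanced.enhanced_cpts[spec.name]
        cpts.append(Cpt(node=spec.name, rows={k: r.mean for k, r in ecpt.rows.items()}))
    prov = (enhanced.base.provenance + "; " if enhanced.base.provenance else "")
    return BnModel(
        nodes=enhanced.base.nodes,
        cpts={c.node: c for c in cpts},
        bn_type="aleatory",
        provenance=prov + "collapsed from enhanced model at posterior-mean tables",
    )


def collapse_to_predictive(enhanced: EnhancedBn) -> BnModel:
    """Marginalize parameter uncertainty into the variables.

    For one next observation under independent Dirichlet rows, the
    predictive table equals the posterior mean, so the numbers coincide
    with :func:`collapse_to_aleatory`; the ``predictive`` tag and the
    provenance note record that the resulting probabilities mix aleatory
    and epistemic uncertainty with no clear separation.
    """
    aleatory = collapse_to_aleatory(enhanced)
    prov = (enhanced.base.provenance + "; " if enhanced.base.provenance else "")
    return replace(
        aleatory,
        bn_type="predictive",
        provenance=prov
        + "predictive marginalization of parameter uncertainty into the "
        "variables; no clear separation between epistemic and aleatory "
        "uncertainty remains",
    )


# ---------------------------------------------------------------------------
# Monte-Carlo propagation
# ---------------------------------------------------------------------------


def propagate(
    enhanced: EnhancedBn, query: Query, draws: int, seed: int
) -> QueryUncertainty:
    """Propagate parameter uncertainty to a distribution over the query.

    For each draw: sample tables (:func:`sample_cpts`), then answer the
    query exactly on the sampled network.  Draws under which the evidence
    is inconsistent are dropped and counted; more than 1% dropped raises
    :class:`PropagationError` (conditioning on a near-null event signals a
    structural fault rather than sampling noise).
    """
    if draws < 1:
        raise InputError("draws must be >= 1")
    rng = np.random.default_rng(seed)
    samples: list[float] = []
    dropped = 0
    for _ in range(draws):
        model = sample_cpts(enhanced, rng)
        try:
            samples.append(eliminate_query(model, query))
        except InconsistentEvidenceError:
            dropped += 1
    if not samples:
        raise PropagationError(
            f"evidence inconsistent in every one of {draws} sampled networks"
        )
    if dropped / draws > MAX_DROPPED_FRACTION:
        raise PropagationError(
            f"{dropped}/{draws} draws dropped for inconsistent evidence "
            f"(> {MAX_DROPPED_FRACTION:.0%}); check the model for structural zeros"
        )
    return QueryUncertainty(
        samples=tuple(samples),
        draw_count=len(samples),
        seed=seed,
        query=query,
        dropped=dropped,
    )


COMPOSITE_CAVEAT = (
    "The mean is a composite probability: an unknown mixture of aleatory "
    "and epistemic uncertainty. It masks whether the risk is a well-known "
    "probability from a highly variable system or an uncertain probability; "
    "report the distribution or an interval alongside it."
)


def summarize(
    qu: QueryUncertainty,
    thresholds: Sequence[float] = (),
    interval_levels: Sequence[float] = (0.90,),
) -> dict:
    """Summarize a query-probability distribution for reporting.

    Returns a plain dict with the composite-probability mean (caveat text
    attached), equal-tailed probability intervals at the requested levels,
    the empirical certainty P(P_f < threshold) for each threshold, and
    rendered certainty statements of the form
    "we are C% certain that the <query> is less than T%".
    """
    if qu.draw_count == 0:
        raise InputError("cannot summarize an empty sample")
    x = np.asarray(qu.samples)
    intervals = {}
    for level in interval_levels:
        if not 0 < level < 1:
            raise InputError(f"interval level must be in (0, 1), got {level}")
        lo, hi = np.quantile(x, [(1 - level) / 2, 1 - (1 - level) / 2])
        intervals[float(level)] = (float(lo), float(hi))
    certainty = {float(t): float(np.mean(x < t)) for t in thresholds}
    statements = [
        "we are {:.6g}% certain that the {} is less than {:.6g}%".format(
            100 * c, qu.query.describe(), 100 * t
        )
        for t, c in certainty.items()
    ]
    return {
        "composite_probability": float(x.mean()),
        "composite_caveat": COMPOSITE_CAVEAT,
        "intervals": intervals,
        "certainty": certainty,
        "statements": statements,
        "draw_count": qu.draw_count,
        "dropped": qu.dropped,
        "seed": qu.seed,
        "query": qu.query.describe(),
    }
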