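"""Discretize continuous hierarchical variability models into table rows.

A Bayesian hierarchical model of a continuous assessment variable X has a
sampling distribution (variability, e.g. X ~ Exponential(lambda)) and a
prior over its parameter (epistemic uncertainty, e.g. lambda ~ LogNormal).
Given bin edges, three constructions are offered:

* *aleatory* — plug in the best-estimate parameter and take CDF differences
  per bin: the table probabilities ``t``;
* *predictive* — average the bin masses over parameter draws from the
  prior: the marginal of the next observation, mixing variability with
  parameter uncertainty;
* *enhanced* — moment-match a Dirichlet to the distribution of bin-mass
  vectors induced by the prior, yielding a mean ``t`` and an equivalent
  sample size ``s`` for an enhanced-network row.

Bins are left-closed right-open ``[a, b)``; the final edge may be +inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .bn_core import InputError, SchemaError, UbnError
from .param_uncertainty import SENTINEL, DirichletRow

COVERAGE_TOL = 1e-9
MAX_REJECTION_FRACTION = 0.01

VARIABILITY_FAMILIES = ("exponential", "normal", "lognormal", "gamma", "poisson")
PRIOR_FAMILIES = ("lognormal", "normal", "gamma", "uniform")


class CoverageError(UbnError):
    """Bin edges fail to cover the distribution's support."""


@dataclass(frozen=True)
class VariabilityModel:
    """A parametric sampling distribution for a continuous/count variable.

    ``point_estimate`` holds the best-estimate parameter values keyed by
    ``parameter_names`` — e.g. ``exponential`` with ``rate`` lambda,
    ``normal`` with ``mean``/``sd``, ``gamma`` with ``shape``/``rate``,
    ``lognormal`` with log-scale ``mu``/``sigma``, ``poisson`` with ``mu``.
    """

    family: str
    parameter_names: tuple[str, ...]
    point_estimate: Mapping[str, float]

    _REQUIRED = {
        "exponential": ("rate",),
        "normal": ("mean", "sd"),
        "lognormal": ("mu", "sigma"),
        "gamma": ("shape", "rate"),
        "poisson": ("mu",),
    }

    def __post_init__(self) -> None:
        if self.family not in VARIABILITY_FAMILIES:
            raise SchemaError(f"unknown family {self.family!r}")
        object.__setattr__(self, "parameter_names", tuple(self.parameter_names))
        object.__setattr__(self, "point_estimate", dict(self.point_estimate))
        required = set(self._REQUIRED[self.family])
        if set(self.parameter_names) != required:
            raise SchemaError(
                f"family {self.family!r} needs parameters {sorted(required)}, "
                f"got {list(self.parameter_names)}"
            )
        self.validate_params(self.point_estimate)

    def validate_params(self, params: Mapping[str, float]) -> None:
        f = self.family
        if f == "exponential" and params["rate"] <= 0:
            raise InputError("exponential rate must be > 0")
        if f == "normal" and params["sd"] <= 0:
            raise InputError("normal sd must be > 0")
        if f == "lognormal" and params["sigma"] <= 0:
            raise InputError("lognormal sigma must be > 0")
        if f == "gamma" and (params["shape"] <= 0 or params["rate"] <= 0):
            raise InputError("gamma shape and rate must be > 0")
        if f == "poisson" and params["mu"] <= 0:
            raise InputError("poisson mu must be > 0")

    def params_valid(self, params: Mapping[str, float]) -> bool:
        try:
            self.validate_params(params)
        except InputError:
            return False
        return True

    def support(self) -> tuple[float, float]:
        return (-math.inf, math.inf) if self.family == "normal" else (0.0, math.inf)

    def cdf(self, x: float, params: Mapping[str, np.ndarray | float]) -> np.ndarray | float:
        """CDF at x; parameter values may be arrays (vectorized over draws)."""
        f = self.family
        if f == "exponential":
            return stats.expon.cdf(x, scale=1.0 / np.asarray(params["rate"]))
        if f == "normal":
            return stats.norm.cdf(x, loc=params["mean"], scale=params["sd"])
        if f == "lognormal":
            return stats.lognorm.cdf(x, s=params["sigma"], scale=np.exp(params["mu"]))
        if f == "gamma":
            return stats.gamma.cdf(x, a=params["shape"], scale=1.0 / np.asarray(params["rate"]))
        if f == "poisson":
            # half-open bins: mass of [a, b) = F(b-) - F(a-); nudge below the
            # edge so integer edges land in the bin to their right
            return stats.poisson.cdf(np.nextafter(x, -math.inf), mu=params["mu"])
        raise SchemaError(f"unknown family {f!r}")


@dataclass(frozen=True)
class ParameterPrior:
    """Epistemic prior over one named parameter of a variability model.

    For a lognormal prior ``scale_convention`` is mandatory: ``"log"``
    means the hyperparameters ``mu``/``sigma`` are the log-scale mean and
    standard deviation; ``"natural"`` means ``mean``/``sd`` are the
    natural-scale moments (converted internally).
    """

    family: str
    hyperparameters: Mapping[str, float]
    parameter: str = ""
    scale_convention: str | None = None  # required for lognormal

    def __post_init__(self) -> None:
        if self.family not in PRIOR_FAMILIES:
            raise SchemaError(f"unknown prior family {self.family!r}")
        object.__setattr__(self, "hyperparameters", dict(self.hyperparameters))
        h = self.hyperparameters
        if self.family == "lognormal":
            if self.scale_convention not in ("log", "natural"):
                raise SchemaError(
                    "lognormal prior requires scale_convention='log' (mu, sigma "
                    "are log-scale) or 'natural' (mean, sd are natural-scale)"
                )
            keys = {"mu", "sigma"} if self.scale_convention == "log" else {"mean", "sd"}
            if set(h) != keys:
                raise SchemaError(f"lognormal/{self.scale_convention} needs {sorted(keys)}")
            if (h.get("sigma", h.get("sd", 1.0))) <= 0:
                raise SchemaError("lognormal spread hyperparameter must be > 0")
        elif self.family == "normal":
            if set(h) != {"mean", "sd"} or h["sd"] <= 0:
                raise SchemaError("normal prior needs mean, sd > 0")
        elif self.family == "gamma":
            if set(h) != {"shape", "rate"} or h["shape"] <= 0 or h["rate"] <= 0:
                raise SchemaError("gamma prior needs shape, rate > 0")
        elif self.family == "uniform":
            if set(h) != {"low", "high"} or not h["low"] < h["high"]:
                raise SchemaError("uniform prior needs low < high")

    @property
    def is_degenerate(self) -> bool:
        return False

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        h = self.hyperparameters
        if self.family == "lognormal":
            if self.scale_convention == "log":
                mu, sigma = h["mu"], h["sigma"]
            else:
                m, sd = h["mean"], h["sd"]
                if m <= 0:
                    raise SchemaError("natural-scale lognormal mean must be > 0")
                sigma = math.sqrt(math.log1p((sd / m) ** 2))
                mu = math.log(m) - sigma**2 / 2
            return rng.lognormal(mean=mu, sigma=sigma, size=n)
        if self.family == "normal":
            return rng.normal(h["mean"], h["sd"], size=n)
        if self.family == "gamma":
            return rng.gamma(h["shape"], 1.0 / h["rate"], size=n)
        if self.family == "uniform":
            return rng.uniform(h["low"], h["high"], size=n)
        raise SchemaError(f"unknown prior family {self.family!r}")


@dataclass(frozen=True)
class DegeneratePrior(ParameterPrior):
    """A point-mass prior at a fixed value (no parameter uncertainty)."""

    def __init__(self, value: float, parameter: str = "") -> None:
        object.__setattr__(self, "family", "uniform")
        object.__setattr__(self, "hyperparameters", {"low": value, "high": value})
        object.__setattr__(self, "parameter", parameter)
        object.__setattr__(self, "scale_convention", None)

    @property
    def is_degenerate(self) -> bool:
        return True

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.full(n, self.hyperparameters["low"])


@dataclass(frozen=True)
class Binning:
    """Strictly increasing bin edges; bins are ``[edge_k, edge_{k+1})``."""

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        if len(edges) < 3:
            raise SchemaError("need >= 2 bins (>= 3 edges)")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise SchemaError("edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def labels(self) -> tuple[str, ...]:
        def fmt(x: float) -> str:
            if math.isinf(x):
                return "inf" if x > 0 else "-inf"
            return f"{x:g}"
        return tuple(
            f"[{fmt(a)},{fmt(b)})" for a, b in zip(self.edges, self.edges[1:])
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _bin_masses(
    vm: VariabilityModel, params: Mapping[str, np.ndarray | float], bins: Binning
) -> np.ndarray:
    """Per-bin CDF differences; last axis = bins, leading axes = draws."""
    cdfs = [np.asarray(vm.cdf(e, params)) for e in bins.edges]
    return np.stack([b - a for a, b in zip(cdfs, cdfs[1:])], axis=-1)


def discretize_variability(vm: VariabilityModel, bins: Binning) -> np.ndarray:
    """Plug-in (aleatory) table probabilities at the best-estimate parameter.

    ``t_k = F(b_{k+1}) - F(b_k)`` at the point estimate.  Raises
    :class:`CoverageError` if the bins leave mass outside their union.
    """
    t = _bin_masses(vm, vm.point_estimate, bins)
    missing = 1.0 - float(t.sum())
    if missing > COVERAGE_TOL:
        raise CoverageError(
            f"bins cover only {float(t.sum()):.12g} of the support "
            f"(missing mass {missing:.3g}); extend the edges"
        )
    return t / t.sum()


def _predictive_draws(
    vm: VariabilityModel,
    prior: ParameterPrior,
    bins: Binning,
    draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Matrix of per-draw bin-mass vectors (draws x bins), with rejection
    of invalid sampled parameter values (> 1% rejections is an error)."""
    target = prior.parameter or vm.parameter_names[0]
    if target not in vm.parameter_names:
        raise InputError(f"prior parameter {target!r} not in {vm.parameter_names}")
    values = prior.sample(draws, rng)
    valid = np.ones(draws, dtype=bool)
    for i, v in enumerate(values):
        params = dict(vm.point_estimate)
        params[target] = float(v)
        if not vm.params_valid(params):
            valid[i] = False
    rejected = int((~valid).sum())
    if draws - rejected == 0:
        raise InputError("every sampled parameter value was invalid for the family")
    if rejected / draws > MAX_REJECTION_FRACTION:
        raise InputError(
            f"{rejected}/{draws} sampled parameter values invalid "
            f"(> {MAX_REJECTION_FRACTION:.0%}); the prior puts substantial mass "
            "outside the parameter's domain"
        )
    params = dict(vm.point_estimate)
    params[target] = values[valid]
    masses = _bin_masses(vm, params, bins)
    missing = 1.0 - masses.sum(axis=-1)
    if float(missing.max()) > COVERAGE_TOL:
        raise CoverageError(
            f"bins leave mass up to {float(missing.max()):.3g} uncovered for some "
            "sampled parameters; extend the edges"
        )
    return masses / masses.sum(axis=-1, keepdims=True)


def discretize_predictive(
    vm: VariabilityModel,
    prior: ParameterPrior,
    bins: Binning,
    draws: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Predictive table: bin masses averaged over parameter draws.

    Returns ``(t, se)`` where ``t`` is the per-bin predictive probability
    and ``se`` the Monte-Carlo standard error per bin.  With a degenerate
    prior this equals :func:`discretize_variability` exactly.
    """
    if draws < 1000:
        raise InputError("predictive discretization needs >= 1000 draws")
    rng = np.random.default_rng(seed)
    masses = _predictive_draws(vm, prior, bins, draws, rng)
    t = masses.mean(axis=0)
    se = masses.std(axis=0, ddof=1) / math.sqrt(masses.shape[0])
    return t / t.sum(), se


def enhanced_from_prior(
    vm: VariabilityModel,
    prior: ParameterPrior,
    bins: Binning,
    draws: int = 10_000,
    seed: int = 0,
) -> tuple[DirichletRow, float]:
    """Moment-matched Dirichlet row for the prior-induced table uncertainty.

    The Dirichlet mean is the empirical mean of the sampled bin-mass
    vectors; the equivalent sample size comes from the Dirichlet variance
    identity ``Var_k = t_k (1 - t_k) / (s + 1)``, averaged over bins:
    ``s + 1 = mean_k [ t_k (1 - t_k) / Var_k ]``.

    Returns ``(row, diagnostic)`` where the diagnostic is the maximum
    absolute deviation between the empirical per-bin variance and the
    fitted Dirichlet variance.  A prior with zero empirical variance in
    every bin yields a sentinel (point-mass) row with diagnostic 0.
    """
    if draws < 1000:
        raise InputError("enhanced fitting needs >= 1000 draws")
    rng = np.random.default_rng(seed)
    masses = _predictive_draws(vm, prior, bins, draws, rng)
    t = masses.mean(axis=0)
    var = masses.var(axis=0, ddof=1)
    if (var <= 0).all():
        return DirichletRow(mean=tuple(t / t.sum()), equivalent_sample_size=SENTINEL), 0.0
    pos = var > 0
    s = float(np.mean(t[pos] * (1 - t[pos]) / var[pos])) - 1.0
    if s <= 0:
        raise InputError(
            "moment matching produced a nonpositive equivalent sample size; "
            "the bin-mass distribution is too dispersed for a Dirichlet fit"
        )
    fitted_var = t * (1 - t) / (s + 1.0)
    diagnostic = float(np.max(np.abs(fitted_var - var)))
    return DirichletRow(mean=tuple(t / t.sum()), equivalent_sample_size=s), diagnostic
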