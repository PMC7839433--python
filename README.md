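# ubn — uncertainty-aware discrete Bayesian networks for risk assessment

`ubn` is a Python library and command-line tool for discrete Bayesian
networks (BNs) whose purpose is not just to compute probabilities but to be
explicit about **what kind of uncertainty** those probabilities express.
It is aimed at environmental and epidemiological risk assessors who use
desk-scale BNs to estimate the probability of an adverse event and need to
communicate how confident anyone should be in that number.

## The problem

A conditional probability table (CPT) entry can mean three different
things: a subjective degree of belief about a unique event (*epistemic*),
a best-estimate relative frequency for a sampling event (*aleatory*), or a
predictive mixture of the two. A plain BN cannot tell you which, and it has
no slot at all for uncertainty about its own table probabilities or its
own structure. When everything is folded into one number, the probability
of the adverse event becomes a *composite probability* — an unknown mixture
of variability and ignorance — and a decision maker cannot distinguish a
well-understood risky system from a poorly understood one.

## What the package does

* **Typed networks** (`bn_core`): validated discrete BNs tagged
  `epistemic | aleatory | predictive`, plus a six-criterion classification
  helper that maps answers about a network (unique vs sampling event,
  certain vs uncertain quantities, informed by expert/data/both, ...) to
  the appropriate tag with a written rationale.
* **Exact inference** (`inference`): variable elimination for
  `P(target ∈ S | evidence)` under hard and virtual (likelihood) evidence,
  with a brute-force enumeration oracle for verification. Conditioning on a
  zero-probability event is an error, never a silent NaN.
* **Enhanced BNs** (`param_uncertainty`): each table row `t` carries a
  Dirichlet model with equivalent sample size `s` (concentration
  `α = s·t`). Supports conjugate case learning (`α' = α + n`), collapsing
  to posterior-mean aleatory or predictive networks, and Monte-Carlo
  propagation: sample tables, re-answer the query, and summarize the
  resulting distribution over the query probability as a mean (flagged
  composite), equal-tailed probability intervals, and certainty statements
  of the form *"we are 90% certain that the risk is less than 5%"*.
* **Credal networks** (`credal`): interval-valued rows, exact lower/upper
  query bounds by vertex enumeration of the interval credal sets (with an
  inner sampling fallback), and the imprecise Dirichlet model
  `[n_k/(N+s), (n_k+s)/(N+s)]` for learning intervals from counts.
* **Hierarchical discretization** (`hierarchical_discretize`): turn a
  continuous variability model (e.g. `X ~ Exponential(λ)`) with a parameter
  prior (e.g. `λ ~ LogNormal(2, 0.5)` on the log scale) into aleatory,
  predictive, or Dirichlet-enhanced table rows over given bin edges.
* **Structure ensembles** (`ensemble`): model averaging with expert or
  likelihood-derived weights, unaggregated uncertainty scenarios, and a
  minimax robust-decision scan across scenario models.
* **Reporting** (`reporting`): assessment reports pairing direct
  uncertainty (point / distribution / bounds / scenario range) with a
  caveat ledger over the six locations of epistemic uncertainty
  (structure, parameters, expert judgment, data, management scenarios,
  output); all six locations are always rendered.
* **Formats** (`io_formats`): XMLBIF 0.3 for plain networks; a YAML
  dialect (UBN-YAML) for enhanced/credal payloads and caveats; CSV case
  files; a seeded random-fixture generator.

## Worked example

A two-node aleatory network (pesticide stressor → population decline) with
Dirichlet uncertainty on its tables (`s = 10` for the stressor node,
`s = 20` for the decline node):

```python
from ubn import *

stressor = NodeSpec("Stressor", ("high", "low"))
decline = NodeSpec("Decline", ("yes", "no"), parents=("Stressor",))
model = build_network(
    [stressor, decline],
    [Cpt("Stressor", {(): (0.3, 0.7)}),
     Cpt("Decline", {("high",): (0.4, 0.6), ("low",): (0.05, 0.95)})],
)
enhanced = make_enhanced_bn(model, {"Stressor": 10.0, "Decline": 20.0})
write_ubn(enhanced, "river.yaml")
```

Propagating the parameter uncertainty to the adverse-event query:

```sh
$ ubn propagate --model river.yaml --target Decline --event yes \
      --draws 5000 --seed 1 --threshold 0.25 --level 0.9
query: P(Decline in {yes})
composite probability (mean): 0.154495
  caveat: The mean is a composite probability: an unknown mixture of aleatory and epistemic uncertainty. ...
90% probability interval: [0.058997, 0.281078]
we are 90.34% certain that the P(Decline in {yes}) is less than 25%
```

The point query at the mean tables would be
`0.3·0.4 + 0.7·0.05 = 0.155`; the propagation shows that with these
equivalent sample sizes the assessor's uncertainty about that probability
spans roughly 0.06–0.28 at the 90% level, and the certainty statement is
the form in which such a result should be communicated. The mean alone is
explicitly flagged as a composite probability.

The same enhanced model can be viewed as a credal network
(`from_enhanced(enhanced, level=0.9)`) and queried for bounds with
`ubn bounds`, or compared against structural alternatives with
`ubn scenarios` / `ubn robust`.

## Scope

The package targets desk-scale networks (a handful to a few dozen nodes).
Out of scope by design: continuous (non-discretized) inference, structure
learning from data, decision/utility nodes, approximate inference for
plain models, learning from incomplete cases, and non-interval credal
sets. See `docs/methods.md` for the model details and the reasoning behind
the main design choices.
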