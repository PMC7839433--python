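# Methods

This note documents the models and procedures implemented in `ubn`, their
assumptions, the parameters that matter, the synthetic-data generator used
throughout the tests, and the design choices that were genuinely open.

## Networks and their uncertainty types

A network is a DAG of finite-state nodes, each with one probability vector
per parent-state configuration (row keys are ordered tuples following the
declared parent order; states are addressed in declared order). The joint
distribution is the chain-rule product of row entries. Rows must sum to 1
within 1e-9 on input; renormalization happens only on explicit request
(`renormalize_cpt`), never silently, because a row that fails to normalize
usually indicates a data-entry error that should surface.

The `bn_type` tag records the interpretation of the probabilities:

* **epistemic** — subjective degrees of belief about a unique event or
  unknown quantity; the network is a belief network for probabilistic
  reasoning, and parameter uncertainty is typically already expressed by
  the node probabilities themselves;
* **aleatory** — best-estimate relative frequencies for a sampling event;
  parameter uncertainty lives *outside* the network and must be treated
  separately (enhanced model, credal bounds, or scenarios);
* **predictive** — marginals in which parameter uncertainty has been
  integrated into the variables; a mixture of variability and ignorance in
  unknown proportion, flagged as such wherever a single number is reported.

The classification helper asks six questions. Three of them (unique vs
sampling event; certain vs uncertain quantities; informed by expert, data,
or both) are the criteria spelled out in the risk-assessment literature
this design follows. The remaining three (parameters treated as known;
case learning performed inside the network; parameter uncertainty
marginalized into the variables) are a reconstruction from the discussion
of predictive networks in that literature, not a printed checklist; they
are the flags needed to separate the aleatory and predictive cases. The
mapping is total: every combination of answers yields a tag, and
combinations the scheme treats as contradictory (e.g. a unique-event model
over quantities declared certain) yield the dominant tag plus an explicit
warning in the rationale rather than an error, so the helper can be used
on messy real descriptions.

## Exact inference

Queries `P(target ∈ S | evidence)` are answered by variable elimination
over table factors. The elimination order is the min-degree heuristic with
lexicographic tie-breaking, which makes factor operations (and timings)
reproducible across runs. Virtual evidence is a non-negative likelihood
vector multiplied into the node's factor before elimination; hard evidence
is the one-hot special case, and the two are interchangeable by
construction (likelihood vectors are invariant to positive scaling).
Conjunction events over several nodes are handled by indicator factors.

Conditioning on an event of zero probability raises
`InconsistentEvidenceError` rather than returning 0/0: in a risk
assessment, a null conditioning event signals a structural zero in the
model colliding with an observation, which is a modeling fault the analyst
must see.

Every query is computed fresh — there is no junction-tree cache. For the
desk-scale networks this package targets (≲ 20 nodes, a few states each),
caching would be premature complexity. A brute-force enumeration oracle
(`enumerate_query`, refused above 10⁶ configurations) computes the same
quantity by summing weighted joint probabilities over all assignments; the
test suite holds the two routes to |Δ| < 1e-10 on hundreds of seeded
networks.

## Enhanced networks (Dirichlet rows)

An enhanced network attaches to each table row a Dirichlet model with mean
`t` and equivalent sample size `s` (concentration `α = s·t`). Rows are
mutually independent across parent configurations and across nodes —
global parameter independence, the standard assumption for Dirichlet BNs;
no cross-row coupling is offered.

Key behaviors and choices:

* **Zero mean entries with finite `s` are rejected**, not jittered: a zero
  entry would give a zero concentration, and silently inventing prior mass
  for an impossible state misstates the assessor's uncertainty. The user
  must either use the sentinel or state a small positive mass explicitly.
* **The point-mass sentinel is `s = ∞`** (`SENTINEL = math.inf`), an
  explicit flag rather than a large float, so sentinel rows sample to
  their mean bit-exactly.
* **Case learning is conjugate**: for complete cases, each row's posterior
  is `α' = α + n` with `n` the per-state counts under that row's parent
  configuration, and `s' = s + N` with `N` the number of matching cases.
  Concentrations are carried exactly (the row caches `α` rather than
  recomputing `s·t`), so the update is exact in floating point, which the
  tests assert with zero tolerance.
* **Collapsing**: `collapse_to_aleatory` sets rows to their posterior
  means `α/Σα`. `collapse_to_predictive` produces numerically identical
  tables — for a single next observation under independent Dirichlet rows
  the predictive distribution equals the posterior mean — so the
  `predictive` tag and a provenance note (no clear separation between
  epistemic and aleatory uncertainty remains) carry the distinction, not
  the numbers.
* **Propagation** samples one table per row per draw, answers the query
  exactly on each sampled network, and returns all draws. Draws whose
  evidence is inconsistent under the sampled tables are dropped and
  counted; if more than 1% of draws are dropped the run errors out. The
  1% policy is this package's choice: occasional zero-mass draws can arise
  from sampled near-zeros, but a high rate means the evidence conflicts
  with the model structurally and averaging over the survivors would
  quietly change the question.
* **Summaries** report the sample mean labelled as a composite probability
  with an attached caveat, equal-tailed probability intervals (chosen over
  HPD intervals because they are order-statistic simple and match the
  probability-interval summaries customary in risk reporting), empirical
  certainties `P(P_f < threshold)`, and rendered statements
  ("we are C% certain that the … is less than T%").

For queries without evidence the query probability is multilinear in the
independent rows, so the Monte-Carlo mean converges to the query at the
mean tables; the tests assert agreement within three standard errors.
Under evidence the query is a ratio and this identity fails; the tests
assert only that the collapsed query lies inside the sampled envelope.

Parameter nodes are deliberately **not** offered inside the network:
querying a network that contains its own parameter nodes risks updating
the parameters through ordinary evidence propagation, conflating
inference about the world with inference about the model.

## Credal networks

A credal network replaces each row with closed per-state intervals,
defining a separately specified interval credal set (non-empty iff
`Σ lower ≤ 1 ≤ Σ upper`). Query bounds:

* **Vertex enumeration** (exact for this family): the extreme points of
  each row's credal set are generated by the permutation-greedy
  construction — for each state ordering, assign each state the largest
  value its upper bound and the remaining lower bounds allow — with
  deduplication. The bounds are the min/max of the exact conditional query
  over the Cartesian product of row vertices; the ratio is evaluated whole
  at each vertex combination rather than bounding numerator and
  denominator separately, which would not be tight. Rows with more than 5
  states refuse vertex mode (vertex counts grow factorially) and the total
  combination budget is 10⁶.
* **Inner sampling**: uniform rejection sampling of valid tables inside
  the intervals (uniform on the simplex, accept if inside the box); rows
  too narrow for rejection to hit fall back to random convex combinations
  of the row's vertices, which are still inside the credal set. The
  resulting bounds are an inner (optimistic) approximation, flagged as
  such, and always contained in the vertex bounds.

The imprecise Dirichlet model maps counts to intervals
`[n_k/(N+s), (n_k+s)/(N+s)]`; the hyperparameter defaults to `s = 2`, the
common convention in the IDM literature, and is configurable. Intervals
are vacuous at `N = 0` and shrink toward the relative frequencies at rate
`s/(N+s)`.

`from_enhanced` builds a credal view of an enhanced model from the central
(equal-tailed) credible intervals of each row's Dirichlet marginals — each
state's marginal is Beta(α_k, s−α_k) — at a chosen level. The result is
tagged `epistemic_credal` (bounds widening a subjective probability); the
aleatory/epistemic credal flavor is interpretive metadata only, since the
two flavors compute identically.

## Hierarchical discretization

Given a sampling family (exponential, normal, lognormal, gamma, Poisson),
a point estimate, and strictly increasing bin edges (left-closed
right-open, first/last edge may be infinite):

* the **aleatory** table is the CDF difference per bin at the point
  estimate; bins that fail to cover the support raise a coverage error
  reporting the missing mass;
* the **predictive** table averages the bin masses over parameter draws
  from a prior (lognormal, normal, gamma, or uniform over one named
  parameter), reporting a Monte-Carlo standard error per bin; sampled
  parameter values invalid for the family (e.g. a negative rate from a
  normal prior) are rejected, with an error above 1% rejections;
* the **enhanced** row fits a Dirichlet to the prior-induced distribution
  of bin-mass vectors by moment matching: the mean vector is the empirical
  mean, and `s + 1 = mean_k[t_k(1−t_k)/Var_k]` from the Dirichlet variance
  identity, with a diagnostic reporting the worst per-bin variance
  mismatch. Moment matching was chosen over maximum likelihood because it
  is closed-form and deterministic; the induced distribution is not
  exactly Dirichlet anyway, and the diagnostic quantifies the
  approximation. A degenerate prior yields a sentinel row.

Lognormal priors require an explicit `scale_convention`: the worked
default (`mu = 2, sigma = 0.5`) is log-scale, but natural-scale moments
(`mean`, `sd`) are accepted and converted. The flag is mandatory because
the two conventions are easily confused and the difference is large; the
package refuses to guess. For Poisson (discrete) families, bin masses are
evaluated just below each edge so integer edges fall into the bin to their
right, consistent with the half-open convention.

The worked example's edges `(0, 1, 2, ∞)` and every number derived from
them are this package's own choices for illustration; with rate `ln 2` the
plug-in table is analytically `(0.5, 0.25, 0.25)`.

## Ensembles and robust decisions

Structural uncertainty cannot be expressed inside one network, so it is
treated with a labelled set of alternative models sharing the query
target (members may differ in nodes, links, and discretization).

* `average_query` computes `Σ w_m P_m(event | evidence)` — averaging
  operates at the level of query results (the output node), not of full
  joints, since members need not share a full node set.
* `likelihood_weights` derives weights `w_m ∝ prior_m · Π P_m(case)` in
  log space from cases over the shared observable subset, with each
  member marginalizing over its private nodes. A member assigning zero
  probability to an observed case gets weight zero with a warning.
* `scenario_query` answers per member and never aggregates, reporting the
  scenario range; this is the right form when assessors cannot or will
  not put probabilities on structures.
* `robust_scan` applies each management alternative (an evidence set) to
  every scenario and ranks alternatives by their worst-case adverse-event
  probability (minimax). Minimax is the single built-in criterion;
  regret-style criteria are out of scope. Evidence naming a node absent
  from a member is an error rather than a silent skip — dropping evidence
  per member would change the question being answered.

## Reporting

An `AssessmentReport` pairs direct uncertainty (point probability,
distribution summary, bounds, scenario results) with a caveat ledger over
six fixed locations: structure, parameters, expert judgment, data,
management scenarios, output. Rendering always lists all six locations,
with "no caveats recorded" for empty ones — the absence of recorded
caveats is information. Any single merged probability sets a composite
flag that cannot be unset silently, and the rendered report states the
definition (an unknown mixture of aleatory and epistemic uncertainty).
The severity scale (note / concern / major) is this package's minimal
ordinal invention for the summary table; caveats remain free text, and no
numeric quality scoring is attempted. The structured rendering
round-trips to an equal report, so reports can be stored and re-rendered.

## File formats

XMLBIF 0.3 carries plain networks only; exporting an enhanced model to
XMLBIF collapses it to posterior means with an explicit warning (the
format has no slot for parameter uncertainty, and lossy export should
never be silent). Table entries are written with parent configurations in
declared parent order, last parent varying fastest, child states in
declared order. UBN-YAML carries plain tables plus optional `enhanced:`
(per-row `t`, `s`, with `s: inf` for sentinels), `credal:` (per-row
`lower`/`upper`), and `caveats:` blocks; a node may carry an enhanced or a
credal payload, never both. Probabilities are serialized as decimal
strings with 17 significant digits, so write→read round-trips are
bit-faithful. Case files are complete-case UTF-8 CSV with a mandatory
header; unknown labels are rejected, never coerced.

## Synthetic data generator

`generate_fixture` produces seeded random networks: a DAG by edge
sampling over a fixed topological order (edge probability = `density`),
uniform state counts in [2, max_states], table rows drawn
Dirichlet(1, …, 1) (uniform on the simplex), optional per-row equivalent
sample sizes drawn uniformly from a range, optional interval widening for
credal fixtures, and optional forward-sampled complete cases. It emulates
the *shape* of desk-scale assessment networks — sparse DAGs, few states,
non-extreme tables. It does not emulate features of real assessment data:
deterministic or near-deterministic CPT rows, label noise, missing cases,
selection effects, or realistic causal magnitudes. Passing tests
therefore demonstrate the correctness of the algorithms under the stated
models, not robustness to those real-data pathologies; near-deterministic
tables in particular can make evidence inconsistency far more common than
the fixtures suggest.

## Problem sizes and numerical choices

The test suite and the acceptance script use networks of 2–6 nodes with
up to 4 states, 10⁴ propagation draws, a 10⁶-draw oracle for the
discretization pipeline, 500 cases for likelihood-weight recovery, and
100 fuzzed round-trip fixtures — sizes at which the enumeration oracle is
cheap and the dual-route checks are exact, matching the desk scale the
package targets. Tolerances: row sums 1e-9; elimination vs enumeration
1e-10; Monte-Carlo agreement 3 standard errors; exact identities (weights,
degenerate credal sets, conjugate updates) 1e-12 or exact. Ties in the
elimination order break lexicographically; quantiles are numpy's default
linear-interpolation order statistics.

## Known limitations

* Inference cost grows with treewidth; no junction tree or caching.
* Vertex enumeration is exponential in the number of uncertain rows and
  factorial in states per row; the 10⁶-combination budget and the 5-state
  row limit keep it honest, and inner sampling is only an inner bound.
* The Dirichlet moment-match is an approximation to the prior-induced
  table distribution; inspect the reported variance diagnostic.
* Learning requires complete cases (no EM); incomplete rows must be
  handled upstream.
* Model averaging operates on query results, not joints; members must
  agree on the target node's states.
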