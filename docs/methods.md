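# Methods

## Setting and design

`adaptmatch` implements an adaptive design for a *prospective matched
case-control trial*: a fixed external control arm of `n_control` patients
already exists (for example the control arm of an earlier randomized
trial), and a treated arm is recruited prospectively.  Because the arms are
not randomized, treated and control patients are compared through 1:1
propensity-score matching, and the quantity that drives the sample-size
planning is the **matching rate** — the fraction of reference-arm patients
for whom a within-caliper partner is found.  The matching rate is unknown
at the planning stage, so the design fixes an interim analysis: after
`n_treated_interim` treated patients have been recruited, the matching rate
is estimated and the treated-arm requirement is recalculated so that, at
the final analysis, (nearly) every control patient finds a partner.

Two interim estimators are implemented.

**Naive method.**  Match all interim treated patients against the full
control arm once; the observed rate `mr` (denominator: the treated arm, the
limiting arm at interim) rescales the requirement to
`ceil(n_control / mr)`.  Because each treated patient can draw on the full
diversity of the control pool, this rate systematically overestimates the
rate achievable at the final analysis, when the treated arm must cover the
controls; the consequence is under-recruitment and a loss of power.

**Resampling CI method** (the proposed design).  Repeat `b` times (default
200): draw `n_treated_interim` controls *without replacement*, fit the
propensity model on the sampled controls plus all interim treated patients,
match 1:1 within the caliper, and record the matching rate (denominator:
the common arm size — the equal-sized groups deliberately bias the estimate
downward).  With the mean resampling rate `mr_bar`, a one-sided lower
confidence limit is formed on the `n_control` scale,

    l_mr = mr_bar − z_{1−α_CI} · sqrt(mr_bar·(1−mr_bar)/n_control),

and the recruitment target is `n_treated_final = ceil(n_control / l_mr)`.
`z_{1−α_CI}` is the standard normal quantile (2.326 / 1.645 / 1.282 for
α_CI = 0.01 / 0.05 / 0.10).  Using `n_control` in the standard error makes
the interval narrow for large control arms, where a high matching rate can
actually be realized.

## Propensity model and matching

The propensity score e(X) = P(z=1 | X) is estimated by maximum-likelihood
logistic regression of the arm indicator on the declared baseline
covariates.  Matching operates on the logit scale, ln(e/(1−e)), with a
caliper of `0.2 ×` the sample standard deviation (ddof = 1) of the pooled
logit scores of all subjects entering that particular match; the caliper is
therefore re-derived inside every interim resample and again at the final
analysis.  Both the multiplier and the covariate list are configurable.

Matching is greedy nearest-neighbour 1:1 **without replacement**: treated
subjects are visited in a random order (seeded), each takes the nearest
still-unmatched control within the caliper, ties go to the lowest control
id.  Without-replacement matching is required by the paired final analysis
(distinct pairs feed a McNemar-type test).  The random processing order
avoids the systematic bias of a fixed order; for distributional summaries
(matching rates, recruited sizes) the order contributes only noise.

The logistic solver is an in-package Newton–Raphson/IRLS routine compiled
with numba, because it sits in the innermost loop of the resampling interim
(b fits per interim, one interim per replication, thousands of replications
per scenario).  Convergence tolerance is 1e-10 on the coefficient update
with at most 50 iterations; a non-converged fit, a singular information
matrix, or any fitted |logit| > 30 (probabilities numerically at 0/1,
i.e. separation) raises a distinct error.  Inside the resampling loop a
failed resample is redrawn once with fresh controls; a second failure
records the rate as missing and the mean uses the available resamples.
Covariates that happen to be constant in a given (re)sample are dropped for
that fit, down to an intercept-only model — in that fully degenerate case
all logits coincide, the caliper is 0, all distances are 0, and the
matching rate is 1.

## Final analysis

The binary outcome is tested one-sidedly (H0: p_control ≥ p_treated vs
H1: p_control < p_treated) on the matched pairs with the McNemar statistic
on discordant counts, z = (n10 − n01)/√(n10+n01), p = 1 − Φ(z), without
continuity correction, at α = 0.05.  The uncorrected one-sided z-test
tracks the mid-p exact binomial tail to within 0.02 for 30+ discordant
pairs; a conservative exact binomial option (`exact=True`) is provided.
The final matching rate uses `n_control` as denominator.

## Synthetic cohorts

The generator emulates the covariate structure of an acute-stroke
periinterventional-management comparison: x1, x2 binary (Bernoulli 0.5 and
0.2), x3 continuous age-like (Normal(70, 15); parameters are (mean, sd)),
arm assignment logistic in x1 and x3 (logit = −0.6 + 0.35·x1 − 0.01·x3,
≈ 26–38% treated), an ASPECTS-like ordinal score x4 (Binomial(10, 0.80)
control / (10, 0.75) treated) and an NIHSS-like severity score x5
(Normal(17, 5) control / Normal(16, 4) treated).  Covariates are
independent given the arm.  Outcomes are Bernoulli(0.5) in both arms under
H0 and logistic (−0.5 + β_z·z + 0.2·x4) under H1, with β_z = 2 / 1 / 0.55
calibrated to ≈80% power for control arms of 50 / 150 / 500.

The propensity model deliberately uses x2, x3, x5 — including x2, which is
*not* in the true assignment model, and omitting x1, which is — so the
simulation carries a realistic degree of model misspecification.

Recruitment is sequential accrual: candidates arrive one at a time, the arm
is Bernoulli from the assignment model, and a candidate is kept only while
its arm's quota is unfilled.  Accepted subjects are i.i.d. draws from the
covariate law conditional on arm, which is the dependence the matching has
to correct.  A generous candidate cap turns degenerate assignment
probabilities into an explicit error rather than a hang.  Outcomes are
generated at recruitment (they are only read at the final analysis, so the
timing is immaterial).

What the generator does **not** emulate: correlated covariates, missing
data, covariate sets beyond x1–x5, secular drift between the external
control trial and the prospective arm, or 1:k matching designs.  Passing
simulations therefore demonstrate the operating characteristics of the
design under clean, independent covariates with a known assignment model —
not robustness to the messier failure modes of real observational data
(the trial-mode loader at least handles missing covariates by listwise
exclusion, mirroring practice).

## Monte-Carlo study

Each replication: recruit `n_control` controls and
`round(s · n_control)` treated (interim fraction `s`, default 1/2), run the
configured interim method, extend the treated arm to `n_treated_final`,
final-match, McNemar-test.  Replication r of a scenario uses the RNG stream
`default_rng([master_seed, r])`, so every scenario is bit-reproducible and
replications are independent.  Aggregates carry Monte-Carlo standard
errors; a scenario aborts if more than 5% of replications fail.

Guards chosen where the procedure is silent:

* `n_treated_interim = round(s · n_control)`, and scenarios with fewer than
  15 interim treated are refused by default (matching partners become hard
  to find below that size; overridable).
* `ceil` in the sample-size rule, so the recruited arm never undershoots
  the computed requirement.
* A floor (default 0.05) clamps `l_mr` before the division, preventing
  unbounded recruitment targets from a tiny or unlucky interim estimate.

**Problem sizes.**  The reference operating characteristics were produced
at 10,000 replications per scenario.  This package's test suite and the
`scripts/acceptance.py` summary rerun them at 500–2,000 replications per
scenario (stated per check), which puts the Monte-Carlo standard error of a
matching-rate mean near 0.002–0.004 and of a rejection rate near 0.5
percentage points — small against the tolerances used.  Defaults in
`ScenarioConfig` keep `n_reps` configurable; 10,000-replication runs
reproduce the published precision when desired.

## Known limitations

* The exact matched pairs of any single run depend on the random treated
  processing order; only distributional quantities are reproducible across
  implementations.
* The design presumes the control arm is the smaller arm at final analysis
  and the treated arm can be extended at will; the maximal per-group size
  is capped by `n_control`, which caps attainable power.
* The normal-approximation CI for the mean resampling rate ignores the
  dependence among resamples drawn from the same control pool; it is used
  as the design prescribes, not as a calibrated frequentist interval.
* For very large control pools (registries) the equal-group resampling
  underestimates the achievable rate; a 1:k design would be more
  appropriate and is out of scope.
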