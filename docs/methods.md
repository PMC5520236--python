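# Methods

This document records the statistical model, the algorithmic and
numerical choices made in this implementation, and their limitations.

## Model

### Dose scale

Raw doses `y_1 < … < y_k` enter the model as centred log doses
`x_i = log(y_i) − (1/k) Σ_j log(y_j)`. Centring removes the collinearity
between intercept and slope that raw log doses would induce and makes
the intercepts interpretable as logits at the geometric-mean dose.

### Outcome model

For a patient at codified dose x with parameters
θ = (μ_E, β_E1, β_E2, μ_T, β_T, ψ):

- efficacy: `logit π_E = μ_E + β_E1 x + β_E2 x²` (the quadratic term
  allows non-monotone, plateauing activity);
- toxicity: `logit π_T = μ_T + β_T x` (monotone when β_T > 0);
- joint distribution of the binary pair (a = efficacy, b = toxicity):

```
π_{a,b} = π_E^a (1−π_E)^{1−a} π_T^b (1−π_T)^{1−b}
          + (−1)^{a+b} · π_E (1−π_E) π_T (1−π_T) · tanh(ψ/2)
```

This Farlie–Gumbel–Morgenstern-type construction always yields a valid
probability table: each independence cell is at least
`π_E(1−π_E)π_T(1−π_T)` times 1, and `|tanh(ψ/2)| < 1`, so no cell can
go negative. Cells are nonetheless clamped at −1e−12 to absorb floating
rounding, and any larger negativity raises an error rather than being
silently truncated.

### Utility

The desirability of an (efficacy, toxicity) pair is

```
u(π_E, π_T) = 1 − ( ((1−π_E)/(1−π*_1E))^p + (π_T/π*_2T)^p )^(1/p)
```

where (π*_1E, 0) and (1, π*_2T) are elicited zero-utility points and p
is chosen so the zero contour passes through a third elicited
indifference point. `solve_contour_p` finds p by bracketed Brent root
finding on `a^p + b^p = 1`; a solution exists and is unique when the
third point lies strictly inside the rectangle spanned by the axis
points (both ratio terms in (0, 1), the left side is strictly
decreasing in p, → 2 as p → 0+ and → max(a,b) < 1 as p → ∞).
`solve_equal_utility_points` inverts the same parameterisation from any
three interior contour points by Newton-type root finding on
(logit π*_1E, logit π*_2T, log p), and self-checks its solution.

### Admissibility and dose selection

A dose is admissible when `Pr(π_E > π̲_E | data) > p_E` and
`Pr(π_T < π̄_T | data) > p_T`. The next cohort receives the admissible
dose maximising posterior mean utility, subject to *no-skip* rules: an
untried dose more than one level above the highest tried dose (or below
the lowest) cannot be assigned. Both directions are independently
configurable because the published design applies the rule in
escalation while the reference software also applies it in
de-escalation. An empty candidate set stops the trial with no dose
selected. Utility ties within 1e−9 select the lower dose and flag the
tie.

With no patients treated, the configured start dose is recommended
without computing a posterior: the decision is protocol-fixed and doing
otherwise would make the first assignment seed-dependent.

## Prior calibration

Clinicians elicit per-dose efficacy and toxicity probabilities
(η_E, η_T) and a target prior effective sample size (ESS).

1. **Means.** `fit_prior_means` least-squares fits the model's mean
   structure to the elicited probabilities on the logit scale (the
   scale on which the model is linear); the association mean is 0. The
   quadratic efficacy curve has 3 parameters and the linear toxicity
   curve 2, so with 4 elicited values per endpoint the fit carries a
   residual (up to 0.046 in probability for the packaged
   configuration); exactly representable elicitations are recovered to
   machine precision.
2. **Spread.** A single common standard deviation σ for the five
   mean-structure parameters (the ψ scale is fixed at 1.0, as the
   association is weakly identified and not elicited) is solved by
   Brent root finding so that the Monte Carlo ESS equals the target.
   The same normal draws (common random numbers) are reused at every σ,
   making the objective smooth and monotone in σ so the root is
   well defined.
3. **ESS definition.** For each dose and endpoint, the prior predictive
   probability draws are moment-matched to a Beta(a, b) via
   `a + b = m(1−m)/v − 1`, and the ESS is the average of `a + b` over
   doses and endpoints. A prior flatter than uniform (ESS < 2 per cell)
   at some dose triggers a warning rather than an error.

Because a weak prior (σ ≈ 2 for the packaged ESS 1.3) is pushed through
the nonlinear logistic transform, the prior *predictive mean*
probabilities are shrunk toward 0.5 relative to the elicited values;
the predictive *medians* equal the fitted elicitation curves. This is a
property of any common-σ normal-on-logit prior, not an implementation
artefact.

## Posterior computation

The posterior is computed by self-normalised importance sampling with
the prior as proposal: draw θ ~ prior, weight by the likelihood,
normalise. This choice is exact in expectation, trivially reproducible
given a seed, has no tuning parameters or convergence diagnostics, and
is fast enough to run thousands of times inside DTP enumeration and
simulation. It is accurate here because trials are small (≤ 30
patients), so the likelihood never concentrates far into the prior
tails. Guard rails:

- minimum 1,000 draws; interactive fits default to 100,000;
- the importance-weight effective sample size `1/Σ w²` is reported, and
  a `DegenerateWeightsWarning` is raised when it falls below 50;
- all-zero weights (data impossible under the model) raise an error.

Validation: on a two-dose toy design whose association prior is
essentially degenerate (so the posterior factorises), importance
sampling agrees with a dense-grid trapezoidal quadrature oracle within
0.02 on all exceedance probabilities. Gauss–Hermite quadrature was
tried and rejected as the oracle: the exceedance integrands are
discontinuous indicators, and node-count-dependent oscillation made the
"oracle" less reliable than the method under test.

### Simulation-grade sample size

Inside whole-trial simulation and DTP-style enumeration the per-decision
sample size defaults to 10,000 draws (package choice, constant
`SIM_N_SAMPLES`). At 10,000 draws a single decision for the packaged
four-dose design takes ~5 ms, so 1,000 replications of a 30-patient
trial (≈ 10 decisions each) complete in about a minute per scenario on
one CPU. The Monte Carlo noise this adds is visible only in
decision-boundary states — exactly the states the ambivalence
diagnostics are designed to flag — and operating characteristics at
10,000 draws match 100,000-draw spot checks well within simulation
error.

## Dose-transition pathways, ambivalence, missing outcomes

- **DTP.** All `C(m+3, 3)` outcome multisets of a cohort of m (20 for
  m = 3) are enumerated in a canonical order (none → both), recursively
  to a horizon. Each node's decision uses a seed derived as
  `sha256(f"{base_seed}|{path}") mod 2³¹`, so published tables are
  exactly re-derivable while distinct pathways are independently
  randomised. Stop decisions prune the subtree.
- **Ambivalence.** `assess_ambivalence` re-runs the decision across
  seeds and reports the tally and modal share. A modal share
  materially below 1 indicates two doses with nearly equal posterior
  utility (or a dose on the admissibility boundary); the posterior
  utility density plots and the overlap coefficient (integral of the
  pointwise minimum of two kernel density estimates) visualise why.
  The correct response is clinical review, not more draws.
- **Missing outcomes.** `resolvable_under_missing` enumerates every
  completion of the pending patients' outcomes (deduplicated as
  multisets) with the same per-pathway seed derivation as the DTP; the
  decision is resolved iff all completions agree.

## Simulation

Scenarios specify true per-dose efficacy/toxicity probabilities and an
optional association on the same `tanh(ψ/2)` scale as the model
(default independent). Patient outcomes are drawn from the implied
four-cell table. Replication i of a run with master seed s uses
`numpy.random.SeedSequence(entropy=s, spawn_key=(i,))`, so aggregate
results are invariant to execution order and to the number of joblib
workers. A minimum of 100 replications is enforced. Within the
replication loop, weight-degeneracy warnings are suppressed: at
simulation-grade sample sizes an occasional degenerate decision is
expected and is part of the behaviour being measured.

Generator realism is limited: outcomes are immediate and binary, there
is no patient heterogeneity, no accrual process, and no outcome
assessment delay. These match the design's own assumptions — the
simulator measures the design's operating characteristics under its own
model class, not clinical reality.

## Numerical and interface choices

- Confidence intervals delegate to
  `statsmodels.stats.proportion.proportion_confint` (methods `beta` and
  `wilson`); the two-sided Clopper–Pearson bound at n events in n
  trials equals `(α/2)^(1/n)` and is verified against that closed form.
- The statsmodels-style split between `EffToxModel` (design + data,
  immutable-by-convention, `extend` returns a new model) and
  `EffToxResults` (one fitted posterior: summaries, admissibility,
  recommendation, report) keeps trial state separate from
  seed-dependent computation.
- The CLI writes a JSON run manifest (config SHA-256, seed, operation,
  version, timestamp, outputs) on every invocation so any artifact can
  be reproduced from its manifest. `recommend` exits 0 for a dose, 10
  for a stop decision, and nonzero on errors, so shell pipelines can
  branch on the decision.
- All tabular outputs are CSV via pandas; figures are written alongside
  the CSV of the data they plot.

## Limitations

- The posterior is importance-sampled, not exact; decisions in
  near-tied states are Monte Carlo noisy by design. Use the ambivalence
  and overlap diagnostics rather than raising the sample size when the
  modal share is low.
- Prior calibration uses a single common σ and a fixed ψ scale; it
  reproduces the target ESS exactly but is not guaranteed to match the
  hyperparameters of other EffTox software, whose calibration
  algorithms differ in unpublished details. Consequently, posterior
  summaries and stop boundaries can differ quantitatively from
  published tables computed under other software's priors, while
  reproducing their qualitative behaviour.
- Efficacy and toxicity are modelled at fixed assessment; time-to-event
  variants of EffTox are out of scope.
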