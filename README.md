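# efftox

A Bayesian seamless phase I/II dose-finding design that selects doses by
trading off efficacy against toxicity, as used for dose-finding trials
in which a drug's activity and its tolerability must be learned jointly
from small cohorts.

Classical phase I designs escalate on toxicity alone and can recommend
a dose with little therapeutic activity. This package implements the
EffTox family of designs: after each cohort of patients, the joint
posterior of each dose's efficacy probability and toxicity probability
is updated, inadmissible doses (too toxic, or too unlikely to work) are
excluded, and the next cohort receives the admissible dose with the
highest posterior mean *utility* — a clinician-elicited trade-off
between efficacy and toxicity. The packaged default configuration is a
four-dose trial (7.5, 15, 30, 45 units) with cohorts of three and a
maximum of 30 patients.

## The model

Doses are codified as centred log doses,
`x_i = log(y_i) − mean_j log(y_j)`. Per-patient binary efficacy and
toxicity outcomes follow logistic regressions

```
logit π_E(x, θ) = μ_E + β_E1 x + β_E2 x²
logit π_T(x, θ) = μ_T + β_T x
```

with the joint distribution of the two outcomes given by a
Farlie–Gumbel–Morgenstern-type association term governed by a parameter
ψ. The six parameters θ = (μ_E, β_E1, β_E2, μ_T, β_T, ψ) have
independent normal priors calibrated from elicited per-dose outcome
probabilities to a target prior effective sample size (ESS).

The utility of an (efficacy, toxicity) probability pair is defined by
an L^p-norm contour through three elicited indifference points:

```
u(π_E, π_T) = 1 − ( ((1−π_E)/(1−π*_1E))^p + (π_T/π*_2T)^p )^(1/p)
```

A dose is **admissible** when `Pr(π_E > π̲_E | data) > p_E` and
`Pr(π_T < π̄_T | data) > p_T`. The design recommends the admissible
dose with maximal posterior mean utility, subject to no-skip rules in
escalation and de-escalation; an empty admissible set stops the trial.

Beyond the core design, the package provides:

- **Dose-transition pathways (DTP)**: enumeration of the design's
  decision for every feasible outcome of the next cohort(s), so the
  design's behaviour can be audited before the trial runs.
- **Dose ambivalence diagnostics**: re-running the Monte Carlo decision
  across seeds, plus posterior-utility density plots and overlap
  coefficients, to detect states where two doses are nearly tied.
- **Missing-outcome resolution**: deciding whether a dose decision is
  already determined when some patients' outcomes are pending.
- **Trial simulation**: operating characteristics (selection
  probabilities, stop probability, patient allocation) under assumed
  true dose-outcome curves.
- **Binomial confidence intervals** (Clopper–Pearson and Wilson) used
  in design discussions of extreme early outcomes.

## Worked example

```python
import efftox as et
from efftox.model import EffToxModel

design = et.matchpoint()          # packaged four-dose configuration
results = EffToxModel.from_path(design, "3NTE").fit(n_samples=100_000, seed=0)
print(results.summary())
```

The outcome path `"3NTE"` means one cohort of three patients at dose
level 3 with outcomes: no event, toxicity only, efficacy only. Output:

```
EffTox posterior summary
  patients observed: 3 / 30
  importance-weight ESS: 42,284 of 100,000 draws

 dose_level  raw_dose  mean_eff  mean_tox  pr_eff_exceeds  pr_tox_below  mean_utility  admissible
          1       7.5     0.311     0.139           0.308         0.875        -0.213        True
          2      15.0     0.294     0.161           0.250         0.889        -0.226        True
          3      30.0     0.374     0.284           0.349         0.739        -0.151        True
          4      45.0     0.457     0.412           0.489         0.522        -0.155        True

  recommendation: dose 3
```

Doses 3 and 4 have nearly equal posterior mean utility here — a classic
dose-ambivalent state. Quantify it:

```python
from efftox.dtp import assess_ambivalence
report = assess_ambivalence(EffToxModel.from_path(design, "3NTE"), n_runs=100)
print(report.recommendations, report.modal_share)
```

The same operations are available from the command line; every
invocation also writes a JSON run manifest for reproducibility:

```
efftox recommend --config design.yaml --outcomes "3NTE" --seed 0 --out run1
efftox dtp --config design.yaml --outcomes "3TTT" --horizon 1 --out dtp1
efftox simulate --config design.yaml --replications 1000 --out oc1
efftox ci 3 3 --method wilson
```

A design YAML names the dose grid, elicited prior probabilities (or an
explicit prior), the utility contour, admissibility rules and cohort
structure; see `src/efftox/data/matchpoint.yaml` for the packaged
example.

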