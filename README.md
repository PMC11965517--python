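# pdelay — model-based diagnostic delay in Parkinson's disease

People with Parkinson's disease (PwPD) arrive at their diagnosis at very
different points of their disease course: some are diagnosed while symptoms
are still mild, others only after substantial progression.  Asking patients
when their first symptoms started is unreliable.  `pdelay` implements a
model-based alternative for longitudinal cohort data: it estimates, for each
individual, how much earlier or later than the cohort average they were
diagnosed, and then asks *which clinical characteristics at the typical time
of diagnosis are associated with that delay*.

The package is written for biostatisticians and movement-disorder researchers
working with long-format visit data (UPDRS, MoCA, SCOPA, Hoehn & Yahr,
questionnaire items, ...).  Because the motivating cohort studies are
access-restricted, the package ships a synthetic-cohort generator that
emulates their designs with known ground truth, so the entire pipeline is
testable offline.

## The model

The core is a latent-time joint mixed-effects model (LTJMM).  For outcome
*k* of individual *i* at visit *j*, with time since clinical diagnosis
*t<sub>ijk</sub>* (years):

```
y_ijk = x_i' β_k + γ_k (t_ijk + δ_i) + α0_ik + α1_ik t_ijk + ε_ijk
```

* `δ_i` — the individual **time shift** (years), shared across outcomes;
  positive values mean the individual was diagnosed *later* than the cohort
  average.  `δ_i ~ N(0, σ_δ²)`.
* `γ_k > 0` — the mean progression slope of outcome *k* on its min-max
  normalized [0, 1] scale ("higher is better" scales such as the MoCA are
  inverted first so every slope is positive).
* `α0_ik, α1_ik` — random intercepts and slopes per individual and outcome,
  jointly Gaussian with a per-outcome 2×2 covariance.
* `x_i` — intercept plus optional covariates (age at diagnosis, sex);
  `ε_ijk ~ N(0, σ_k²)`.

Adding `δ_i` to observed time places everyone on a **common disease
timescale** whose origin (t + δ = 0) is the moment a typical individual is
diagnosed.  Inference is Bayesian: a blocked Gibbs sampler with exact
conditional updates and interweaving moves for the weakly identified
directions, gated by rank-normalized split R-hat < 1.05 across all
parameters.

Downstream stages mirror the analysis workflow:

1. **Manifestation** — align all outcome series on the common timescale,
   fit linear / cumulative-logit / logistic mixed models per outcome, and
   predict each individual's value at s = 0 (the "initial manifestation").
2. **Association** — correlate initial manifestations with the time shifts
   (Pearson / Kendall tau-b / point-biserial by scale), pool outcomes into
   symptom domains with a three-level random-effects meta-analysis
   (DerSimonian–Laird within and across cohorts on Fisher-z effects), and
   correct p-values and CIs across domains with Benjamini–Hochberg.
3. **Validation** — leave-last-measurement-out predictive R², first-visit
   prediction vs a carry-back null model (Wilcoxon signed-rank across
   outcomes), and the Hoehn & Yahr alignment check on a held-out outcome.

## Worked example

```python
from pdelay.simulate import emulate_study_design, generate_cohort
from pdelay.cohort import normalize_outcomes, apply_inclusion_filters
from pdelay.ltjmm import LTJMMSpec, fit, extract_time_shifts

params = emulate_study_design("denovo", n=100, seed=42)
cohort, truth = generate_cohort(params)
prepared = apply_inclusion_filters(normalize_outcomes(cohort))

post = fit(prepared, LTJMMSpec(seed=1))
print(post.convergence)
shifts = extract_time_shifts(post)
print(shifts.head(3).round(2))
```

prints (abridged):

```
{'max_rhat': 1.026, 'min_ess': 183.3, 'n_divergent': 0, 'converged': True, ...}
                point  ci_low  ci_high
individual_id
synthetic-0000  -0.34   -1.57     0.89
synthetic-0001   0.00   -1.27     1.31
synthetic-0002   1.83    0.60     3.11
```

`max_rhat < 1.05` says all four chains agree.  Individual `synthetic-0002`
was diagnosed about 1.8 years *later* than the cohort average (the 95%
credible interval excludes zero); the first two individuals are compatible
with an average-time diagnosis.  On this synthetic cohort the posterior
median shifts correlate 0.88 with the generator's true shifts.

The numbered scripts under `analysis/` run the full study pipeline on three
emulated cohort designs (simulate → fit → manifestation → domain
meta-analysis → validation) and write their tables under `results/`.

## Limitations

Progression is modeled as linear on the normalized scale; shifts are point
estimates (plug-in) in the downstream stages; cohorts are always fitted
separately and only pooled at the meta-analysis level.  See
`docs/methods.md` for the full methods note.
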