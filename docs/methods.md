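# Methods

## Model

For each cohort separately, all continuous outcomes flagged for the joint
fit are min-max normalized on their theoretical score ranges (inverted
scales flipped so progression slopes are positive) and modeled as

y_ijk = x_i' β_k + γ_k (t_ijk + δ_i) + α0_ik + α1_ik t_ijk + ε_ijk,

with ε_ijk ~ N(0, σ_k²), time shifts δ_i ~ N(0, σ_δ²) shared across
outcomes, and per-outcome random intercept/slope pairs
(α0_ik, α1_ik) ~ N(0, Σ_k).  Σ is block-diagonal across outcomes (one 2×2
block per outcome); a full cross-outcome covariance is out of scope and the
synthetic generator uses the same block structure so that recovery
experiments compare like with like.  The design vector x_i always carries an
intercept; age at diagnosis (centered at the cohort mean, for conditioning)
and sex are optional.  A "simplified" covariate-free variant is used
whenever shifts are subsequently correlated with age or compared between
sexes, because the adjusted model partially regresses those effects out.

Times are signed years since clinical diagnosis; pre-diagnosis visits are
negative.  The common disease timescale is s = t + δ, with origin s = 0 at
the typical time of diagnosis; positive δ means later-than-average
diagnosis.

## Priors

All on the normalized [0, 1] outcome scale: β ~ N(0, 1);
γ_k ~ half-normal(0, 0.5) (positivity fixes the timescale direction);
σ_k ~ half-normal(0, 0.5); σ_δ ~ half-normal(0, 5) years (the shift scale is
learned, not fixed); Σ_k parametrized as scales × correlation with
half-normal(0, 0.1) priors on both scales and an LKJ(2) prior on the
correlation.  Half-normal scale priors matter beyond convention here: they
place no floor at zero, which keeps the multiplicative ridge
(γ → γ/c, δ → cδ, plus a compensating random-slope shift leaves the
likelihood invariant) pinned when the data are nearly noise-free.  A prior
with a zero-avoiding floor on the slope-RE scale (e.g. inverse-Wishart)
demonstrably widens that ridge.

## Sampler

The model is conditionally conjugate, so inference uses a blocked Gibbs
sampler rather than generic gradient-based MCMC:

* (δ_i, α0_i·, α1_i·) jointly per individual — Gaussian, solved as batched
  (1+2K)-dimensional systems from per-(individual, outcome) sufficient
  statistics, so an iteration costs O(nK) plus n small Cholesky factors;
* (γ_k | β_k) positive-truncated Gaussian, then (β_k | γ_k) Gaussian;
* σ_k, σ_δ and the Σ_k parameters by 1-D slice sampling;
* exact extra moves along the weakly identified directions: translations of
  δ against every fixed-effect column, the multiplicative γ/δ ridge, the
  γ_k vs mean-random-slope direction, and funnel interweavings that rescale
  each outcome's random effects jointly with their scale.  Without these
  moves the chains stall on the corresponding ridges (R-hat ≈ 1.2–1.9 at
  desk scale); with them the default fit converges comfortably.

Defaults: 4 chains × (1000 warmup + 1000 kept) iterations from
overdispersed moment-based starting values; heavier settings are plain
configuration.  Convergence is gated on rank-normalized split R-hat < 1.05
for every scalar parameter (the classical split form is available and is
clamped at 1 from below, since values under 1 are estimator noise); bulk
effective sample sizes use Geyer's initial monotone sequence.  Gibbs/slice
updates cannot diverge, so the divergence count in the convergence report is
structurally zero.  Runs are deterministic given the seed; chain seeds are
spawned from one seed sequence.

Time-shift point estimates are posterior medians (robust to skew) with
central 95% credible intervals.  With a single outcome the shift is
confounded with that outcome's random intercept; the fit proceeds but warns
that shift intervals are unreliable.  Posterior uncertainty in δ is *not*
propagated downstream: the two-stage design treats δ̂ as plug-in, mirroring
the sequential workflow the pipeline reproduces.

## Manifestation stage

Per outcome, aligned series (s = t + δ̂) are fitted with: continuous —
linear mixed model with correlated random intercept and slope (statsmodels
MixedLM, REML; optimizer fallbacks lbfgs → bfgs → cg → powell; a
noise-free branch detects ~zero pooled OLS residuals and uses exact
per-individual OLS, where the mixed likelihood degenerates); ordinal —
cumulative-logit with a Gaussian random intercept; binary — logistic with a
random intercept (the single-cutpoint case of the same code).  The
ordinal/binary fitter maximizes the Gauss–Hermite marginal likelihood
(25 nodes, BFGS, tolerance 1e-6, ≤200 iterations) and recovers
per-individual effects as empirical-Bayes posterior means on the quadrature
grid.  Random slopes are deliberately omitted on the latent scale: series
are short, predictions are needed at the single point s = 0, and
random-slope ordinal fits are unstable at these sizes.

Predictions at s = 0: continuous — fixed + individual random intercept;
ordinal — probability-weighted expected category (modal category available);
binary — predicted probability.  Each prediction carries an extrapolation
flag set iff s = 0 lies outside that individual's observed aligned range;
with realistic baseline disease durations a majority of predictions are
extrapolations, which is inherent to asking about a time before study entry.
Inclusion minima: ≥2 measurements per individual series and ≥30 individuals
per outcome.

## Association stage

Coefficient by scale: Pearson (continuous), Kendall tau-b (ordinal,
tie-corrected), point-biserial (binary; probability predictions are
dichotomized at 0.5 because the coefficient needs a 0/1 variable — the
undichotomized Pearson value is logged).  For pooling, tau is mapped to its
Pearson equivalent r = sin(πτ/2) and everything is Fisher-z transformed with
SE 1/√(n−3).  Domains are pooled in two random-effects stages
(DerSimonian–Laird, deterministic closed form): outcomes within domain per
cohort, then cohorts within domain.  A domain observed as one outcome in one
cohort passes through unpooled and is flagged.  Across domains, p-values get
Benjamini–Hochberg correction; CIs are recomputed at level 1 − α·k*/m where
k* is the largest BH-accepted rank (k* = 1 when nothing is rejected), so
interval and adjusted-p significance statements coincide.  Positive pooled
coefficients mean greater severity at the typical diagnosis time goes with
later-than-average diagnosis.

Group comparisons (sex, subtype, ...) select the test from the data:
Shapiro–Wilk per group at α = 0.05, then Levene — both normal and equal
variances → Student t; both normal otherwise → Welch; else Mann–Whitney U.
Cohen's d (pooled-sd form) is always reported.  Subgroup splits: sex;
median age on the pooled individual set; early-onset (<50 y) vs late-onset
(>60 y).  All tests are two-sided at α = 0.05.

## Validation stage

Leave-last-out: per individual and fit outcome the measurement with the
largest time is excluded (series that would fall below 2 points are exempt),
the joint model is refitted, and one pooled R² is computed over all excluded
points (per-outcome breakdown reported; an alternative "drop the entire last
visit" reading is configurable).  First-visit check: manifestation models
are refitted without each individual's first visit and predict it at its
aligned time; the null model carries back the value of the earliest visit
≥1 year after the first; both scores use the common subset of individuals
with a valid null prediction, and a two-sided Wilcoxon signed-rank across
outcomes compares the paired R² values (scipy's exact distribution for few
pairs, normal approximation beyond).  Ordinal/binary R² is computed on the
numeric predictions (expected category / probability) against observed
codes.  H&Y check: the Hoehn & Yahr stage never enters the joint fit
(attempting it raises a leakage error); Kendall tau-b of stage against raw
and aligned time is compared — alignment should strengthen it.

## Synthetic cohorts

The generator draws from exactly the inference model (continuous channels),
plus cumulative-logit/logistic latent channels for ordinal/binary outcomes
(latent trajectory of the same linear form plus standard logistic noise
thresholded at fixed cutpoints; raising cutpoints can only lower
categories).  Values are written on raw score scales so normalization is
exercised; continuous values are clipped to [0, 1] after noise (bounded
scores) with the clip fraction logged, since heavy clipping would bias
recovery tests — defaults keep it at a few percent.

Default study conditions: time-shift sd 1.5 y; per-outcome slopes
0.02–0.05 normalized units/year; residual sd 0.06; RE sds 0.05 (intercept)
and 0.012/y (slope), correlation 0.2; age 63 ± 9 y with small positive age
effects; 66% male.  Three design templates set visit schedules, dropout and
baseline disease-duration spread to bracket the emulated designs: de-novo
(14 nominal visits over 7 y, median baseline duration 0.3 y), early-stage
(5 visits / 4 y, 1.2 y), all-stage (4 visits / 4 y, 2.9 y with wide spread).
A fast/slow subtype (35% fast) multiplies slopes by 1.5 and shifts the fast
group's mean δ by +0.4 y, planting the qualitative fast-subtype ↔
later-diagnosis association at a configurable size.  Ordinal cutpoints were
chosen for plausible category occupancy near the diagnosis time (H&Y mostly
I–II at baseline) and are configuration, not estimates.  Visit-time jitter
is Gaussian with a minimal-spacing guard; dropout is permanent with a
per-visit hazard and starts after the second visit, so the emulated
"≥2 visits" inclusion rule holds by construction.

What the generator does *not* emulate: treatment/medication-state effects,
nonlinear (sigmoidal) progression, floor/ceiling measurement artifacts
beyond clipping, informative missingness, and cross-outcome random-effect
correlation.  Passing recovery tests therefore demonstrates correctness of
the inference machinery under the stated model, not robustness to these
real-data features.

## Numerical choices and degenerate inputs

Scale parameters are floored at 1e-7 (sds) purely for numerical safety;
slice sampling operates on log scales.  Constant chains return R-hat 1 by
convention; disagreeing constant chains return infinity.  Correlations are
undefined (error) on zero-variance inputs; identical groups compare as
d = 0, p = 1.  Double normalization is blocked by a cohort-level flag.
Problem sizes in the test suite (n = 30–100 individuals, 20 calibration
replicates, 50 meta-analysis replicates, 2-chain desk fits) were chosen as
the smallest scales at which the checked properties are stable.

## Known limitations

Linearity of progression is assumed throughout.  The overall location and
scale of the shifts are only softly identified (priors resolve the
translation and scaling ridges); consequently shifts are interpretable
relative to the cohort average, not absolutely.  Posterior shift uncertainty
is ignored downstream.  The three-level meta-analysis treats per-cohort
Fisher-z effects as independent given the domain, ignoring the correlation
induced by shared individuals across outcomes of a domain.
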