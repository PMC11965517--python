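"""Synthetic longitudinal PD cohorts with known ground truth.

The generator draws data from the same latent-time joint mixed-effects process
the inference module fits: each continuous outcome follows

    y_ijk = x_i beta_k + gamma_k (t_ijk + delta_i) + a0_ik + a1_ik t_ijk + eps_ijk

on the min-max normalized [0, 1] scale, where ``delta_i`` is the individual
time shift (years; positive = diagnosed later than the cohort average),
``gamma_k > 0`` the mean progression slope, and ``(a0, a1)`` per-individual
random intercepts/slopes.  Ordinal and binary outcomes are generated by
thresholding a latent trajectory of the same linear form with standard
logistic noise (cumulative-logit link; binary is the single-threshold case).

Values are written on the *raw* scale of each outcome (inverted scales such as
the MoCA are flipped back), so that ``cohort.normalize_outcomes`` recovers the
latent normalized trajectories exactly.

Study-design templates mirror the three source designs: a de-novo cohort
(~14 visits over ~7 years, short baseline disease duration), an early-stage
cohort (~5 visits over ~4 years) and an all-stage cohort (~4 visits over
~4 years with a wide baseline disease-duration spread).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, OutcomeSpec, write_cohort

__all__ = [
    "OutcomeParams",
    "SubtypeEffect",
    "SimulationParams",
    "GroundTruth",
    "generate_cohort",
    "emulate_study_design",
    "TEMPLATES",
]


class ParameterError(ValueError):
    """Invalid simulation parameters."""


@dataclass(frozen=True)
class OutcomeParams:
    """Generative parameters for one outcome.

    Continuous outcomes: all quantities on the normalized [0, 1] scale
    (``sigma_eps`` is the residual sd, ``re_sd`` the random intercept/slope
    sds).  Ordinal/binary outcomes: quantities live on the latent logistic
    scale and ``thresholds`` are the (increasing) category cutpoints;
    ``sigma_eps`` is ignored because the logistic noise is the residual.
    """

    spec: OutcomeSpec
    intercept: float
    gamma: float
    beta_age: float = 0.0
    beta_sex: float = 0.0
    re_sd: tuple[float, float] = (0.05, 0.012)
    re_corr: float = 0.2
    sigma_eps: float = 0.06
    thresholds: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ParameterError(f"{self.spec.name}: gamma must be > 0")
        if self.sigma_eps < 0 or min(self.re_sd) < 0:
            raise ParameterError(f"{self.spec.name}: sds must be >= 0")
        if abs(self.re_corr) > 1:
            raise ParameterError(f"{self.spec.name}: |re_corr| must be <= 1")
        if self.spec.scale_kind in ("ordinal", "binary"):
            if len(self.thresholds) == 0:
                raise ParameterError(f"{self.spec.name}: thresholds required")
            if list(self.thresholds) != sorted(self.thresholds):
                raise ParameterError(f"{self.spec.name}: thresholds must increase")

    @property
    def re_cov(self) -> np.ndarray:
        s0, s1 = self.re_sd
        c = self.re_corr * s0 * s1
        return np.array([[s0 * s0, c], [c, s1 * s1]])


@dataclass(frozen=True)
class SubtypeEffect:
    """Fast-progressing subtype: multiply slopes, shift the mean time shift.

    ``delta_offset > 0`` reproduces the finding that the fast subtype is
    diagnosed later than average, at a configurable effect size.
    """

    p_fast: float = 0.35
    slope_multiplier: float = 1.5
    delta_offset: float = 0.4


@dataclass(frozen=True)
class SimulationParams:
    n_individuals: int
    visit_schedule: tuple[float, ...]
    outcomes: tuple[OutcomeParams, ...]
    visit_jitter_sd: float = 0.1
    dropout_prob_per_visit: float = 0.02
    missing_prob: float = 0.02
    sigma_delta: float = 1.5
    baseline_duration_median: float = 0.3
    baseline_duration_log_sd: float = 0.8
    subtype_effect: SubtypeEffect | None = None
    age_mean: float = 63.0
    age_sd: float = 9.0
    p_male: float = 0.66
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ParameterError("n_individuals must be positive")
        if len(self.visit_schedule) == 0:
            raise ParameterError("visit_schedule must be non-empty")
        if len(self.outcomes) == 0:
            raise ParameterError("at least one outcome is required")
        if self.sigma_delta < 0:
            raise ParameterError("sigma_delta must be >= 0")
        for p, name in [
            (self.dropout_prob_per_visit, "dropout_prob_per_visit"),
            (self.missing_prob, "missing_prob"),
            (self.p_male, "p_male"),
        ]:
            if not 0 <= p <= 1:
                raise ParameterError(f"{name} must be a probability")

    def outcome_specs(self) -> dict[str, OutcomeSpec]:
        return {o.spec.name: o.spec for o in self.outcomes}


@dataclass
class GroundTruth:
    """True latent quantities behind a generated cohort."""

    individuals: pd.DataFrame  # index individual_id: true_delta, subtype, age, sex
    random_effects: dict[str, pd.DataFrame]  # outcome -> (a0, a1) per individual
    params: SimulationParams
    clip_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def true_delta(self) -> pd.Series:
        return self.individuals["true_delta"]


def _jittered_times(
    nominal: np.ndarray, jitter_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Jitter visit times, keeping them strictly increasing."""
    t = nominal + rng.normal(0.0, jitter_sd, size=len(nominal))
    t = np.sort(t)
    # enforce a minimal spacing so (id, outcome, time) stays unique
    for j in range(1, len(t)):
        if t[j] - t[j - 1] < 1e-3:
            t[j] = t[j - 1] + 1e-3
    return t


def generate_cohort(
    params: SimulationParams, name: str = "synthetic"
) -> tuple[Cohort, GroundTruth]:
    """Draw one cohort (and its ground truth) from the generative model.

    Deterministic given ``params.seed``.  Continuous values are generated on
    the normalized scale, clipped to [0, 1] (clip fraction recorded in the
    ground truth) and written back on each outcome's raw scale.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_individuals
    ids = [f"{name}-{i:04d}" for i in range(n)]

    age = rng.normal(params.age_mean, params.age_sd, size=n)
    age = np.clip(age, 25.0, None)
    male = rng.random(n) < params.p_male
    sex = np.where(male, "male", "female")

    sub = params.subtype_effect
    if sub is not None:
        fast = rng.random(n) < sub.p_fast
        subtype = np.where(fast, "fast", "slow")
        delta_mean = np.where(fast, sub.delta_offset, 0.0)
        slope_mult = np.where(fast, sub.slope_multiplier, 1.0)
    else:
        subtype = np.full(n, None)
        delta_mean = np.zeros(n)
        slope_mult = np.ones(n)
    delta = rng.normal(delta_mean, params.sigma_delta)

    # visit times (since diagnosis): baseline disease duration + schedule
    if params.baseline_duration_median > 0:
        base_dur = rng.lognormal(
            np.log(params.baseline_duration_median),
            params.baseline_duration_log_sd,
            size=n,
        )
    else:
        base_dur = np.zeros(n)
    schedule = np.asarray(params.visit_schedule, dtype=float)
    visit_times: list[np.ndarray] = []
    for i in range(n):
        t = base_dur[i] + _jittered_times(schedule, params.visit_jitter_sd, rng)
        # permanent dropout, starting after the 2nd visit so the >=2-visit
        # inclusion rule of the emulated designs is met by construction
        n_attend = len(t)
        for v in range(2, len(t)):
            if rng.random() < params.dropout_prob_per_visit:
                n_attend = v
                break
        visit_times.append(t[:n_attend])

    age_c = age - params.age_mean
    re: dict[str, pd.DataFrame] = {}
    clip_frac: dict[str, float] = {}
    rows_id: list[str] = []
    rows_out: list[str] = []
    rows_t: list[float] = []
    rows_v: list[float] = []

    for op in params.outcomes:
        spec = op.spec
        a = rng.multivariate_normal(np.zeros(2), op.re_cov, size=n)
        re[spec.name] = pd.DataFrame(a, index=ids, columns=["a0", "a1"])
        n_clip = 0
        n_tot = 0
        for i in range(n):
            t = visit_times[i]
            gam = op.gamma * slope_mult[i]
            latent = (
                op.intercept
                + op.beta_age * age_c[i]
                + op.beta_sex * male[i]
                + gam * (t + delta[i])
                + a[i, 0]
                + a[i, 1] * t
            )
            if spec.scale_kind == "continuous":
                y = latent + rng.normal(0.0, op.sigma_eps, size=len(t))
                clipped = np.clip(y, 0.0, 1.0)
                n_clip += int(np.sum(clipped != y))
                n_tot += len(y)
                lo, hi = spec.theoretical_min, spec.theoretical_max
                if spec.invert:
                    raw = hi - clipped * (hi - lo)
                else:
                    raw = lo + clipped * (hi - lo)
            else:
                e = rng.logistic(0.0, 1.0, size=len(t))
                cuts = np.asarray(op.thresholds)
                cat = (latent[:, None] + e[:, None] > cuts[None, :]).sum(axis=1)
                raw = spec.theoretical_min + cat
                raw = np.clip(raw, spec.theoretical_min, spec.theoretical_max)
                n_tot += len(t)
            # value-level missingness
            keep = rng.random(len(t)) >= params.missing_prob
            rows_id.extend([ids[i]] * int(keep.sum()))
            rows_out.extend([spec.name] * int(keep.sum()))
            rows_t.extend(np.round(t[keep], 4).tolist())
            rows_v.extend(np.asarray(raw)[keep].tolist())
        clip_frac[spec.name] = n_clip / max(n_tot, 1)

    measurements = pd.DataFrame(
        {
            "individual_id": rows_id,
            "outcome": rows_out,
            "time_years": rows_t,
            "value": rows_v,
        }
    )
    individuals = pd.DataFrame(
        {
            "age_at_diagnosis": age,
            "sex": sex,
            "progression_subtype": subtype,
            "reported_time_to_diagnosis": np.nan,
        },
        index=pd.Index(ids, name="individual_id"),
    )
    cohort = Cohort(
        name=name,
        individuals=individuals,
        measurements=measurements,
        specs=params.outcome_specs(),
    )
    truth = GroundTruth(
        individuals=pd.DataFrame(
            {
                "true_delta": delta,
                "subtype": subtype,
                "age_at_diagnosis": age,
                "sex": sex,
            },
            index=pd.Index(ids, name="individual_id"),
        ),
        random_effects=re,
        params=params,
        clip_fraction=clip_frac,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# study-design templates
# ---------------------------------------------------------------------------


def _default_outcomes() -> tuple[OutcomeParams, ...]:
    """Default mixed outcome battery on realistic PD scales.

    Four continuous outcomes enter the joint latent-time fit (UPDRS I-III and
    the inverted MoCA); the remaining continuous, ordinal and binary outcomes
    are downstream-only, as in the source designs where many questionnaire
    items are analysed but not used for fitting.
    """
    c = lambda name, lo, hi, invert, domain, in_fit: OutcomeSpec(
        name, "continuous", lo, hi, invert, domain, in_fit
    )
    return (
        OutcomeParams(c("updrs1", 0, 52, False, "overall_nonmotor", True),
                      intercept=0.12, gamma=0.030, beta_age=0.0015, beta_sex=0.01),
        OutcomeParams(c("updrs2", 0, 52, False, "motor_adl", True),
                      intercept=0.10, gamma=0.040, beta_age=0.0015, beta_sex=0.01),
        OutcomeParams(c("updrs3", 0, 132, False, "motor", True),
                      intercept=0.16, gamma=0.050, beta_age=0.0020, beta_sex=0.015),
        OutcomeParams(c("moca", 0, 30, True, "cognition", True),
                      intercept=0.10, gamma=0.025, beta_age=0.0025, beta_sex=0.0),
        OutcomeParams(c("scopa", 0, 69, False, "autonomic", False),
                      intercept=0.15, gamma=0.035, beta_age=0.0015, beta_sex=0.0),
        OutcomeParams(c("pigd", 0, 20, False, "pigd", False),
                      intercept=0.10, gamma=0.045, beta_age=0.0020, beta_sex=0.01),
        OutcomeParams(c("tremor", 0, 40, False, "tremor", False),
                      intercept=0.08, gamma=0.020, beta_age=0.0010, beta_sex=0.01),
        OutcomeParams(
            OutcomeSpec("hy", "ordinal", 1, 5, False, "axial", False),
            intercept=0.0, gamma=0.35, beta_age=0.01,
            re_sd=(0.8, 0.15), re_corr=0.2,
            thresholds=(-1.5, 1.5, 3.5, 5.5),
        ),
        OutcomeParams(
            OutcomeSpec("urinary_item", "ordinal", 0, 4, False, "urinary", False),
            intercept=-0.5, gamma=0.25, beta_age=0.01,
            re_sd=(0.9, 0.15), re_corr=0.0,
            thresholds=(-0.5, 1.0, 2.5, 4.0),
        ),
        OutcomeParams(
            OutcomeSpec("constipation", "binary", 0, 1, False, "autonomic", False),
            intercept=-1.2, gamma=0.30, beta_age=0.015,
            re_sd=(1.0, 0.15), re_corr=0.0,
            thresholds=(0.0,),
        ),
    )


TEMPLATES = {
    # ~14 visits over ~7 years, short baseline disease duration
    "denovo": dict(
        visit_schedule=tuple(np.round(np.linspace(0.0, 7.0, 14), 3)),
        visit_jitter_sd=0.08,
        dropout_prob_per_visit=0.015,
        baseline_duration_median=0.3,
        baseline_duration_log_sd=0.8,
    ),
    # ~5 visits over ~4 years
    "earlystage": dict(
        visit_schedule=(0.0, 1.0, 2.0, 3.0, 4.0),
        visit_jitter_sd=0.12,
        dropout_prob_per_visit=0.05,
        baseline_duration_median=1.2,
        baseline_duration_log_sd=0.7,
    ),
    # ~4 visits over ~4 years, wide baseline disease-duration spread
    "allstage": dict(
        visit_schedule=(0.0, 1.33, 2.67, 4.0),
        visit_jitter_sd=0.15,
        dropout_prob_per_visit=0.08,
        baseline_duration_median=2.9,
        baseline_duration_log_sd=1.0,
    ),
}


def emulate_study_design(
    template: str, n: int, seed: int, **overrides
) -> SimulationParams:
    """Parameter preset for one of the emulated study designs.

    ``template`` is one of ``denovo``, ``earlystage``, ``allstage``.  Keyword
    overrides replace any :class:`SimulationParams` field (e.g. a different
    outcome battery or a ``subtype_effect``).
    """
    if template not in TEMPLATES:
        raise ParameterError(
            f"unknown template {template!r}; choose from {sorted(TEMPLATES)}"
        )
    if n <= 0:
        raise ParameterError("n must be positive")
    kwargs: dict = dict(TEMPLATES[template])
    kwargs.update(
        n_individuals=n,
        outcomes=_default_outcomes(),
        subtype_effect=SubtypeEffect(),
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationParams(**kwargs)


def write_simulated_cohort(
    params: SimulationParams, out_dir: str | Path, name: str = "synthetic"
) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort and write it in the cohort I/O format plus truth.csv."""
    cohort, truth = generate_cohort(params, name=name)
    out = Path(out_dir)
    write_cohort(cohort, out)
    truth.individuals.reset_index()[
        ["individual_id", "true_delta", "subtype"]
    ].to_csv(out / "truth.csv", index=False)
    return cohort, truth
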