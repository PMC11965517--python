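"""Latent-time joint mixed-effects model: specification, data and density.

The model for outcome k of individual i at visit j is

    y_ijk = x_i' beta_k + gamma_k (t_ijk + delta_i) + a0_ik + a1_ik t_ijk + e_ijk

with e_ijk ~ N(0, sigma_k^2), delta_i ~ N(0, sigma_delta^2) and
(a0_ik, a1_ik) ~ N(0, Sigma_k) independently across outcomes (block-diagonal
random-effect covariance).  ``x_i`` always contains an intercept; age at
diagnosis (centered at the cohort mean) and sex are optional covariates.
All gamma_k are constrained positive, which fixes the direction of the common
disease timescale: positive delta_i means the individual was diagnosed later
than the cohort average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ..cohort import Cohort, StateError


class IdentifiabilityWarning(UserWarning):
    """Raised when the time shifts are weakly identified (single outcome)."""


@dataclass(frozen=True)
class Priors:
    """Weakly informative priors on the normalized [0, 1] outcome scale.

    ``beta_sd``: normal sd for fixed effects; ``gamma_sd``: half-normal sd for
    the positive mean slopes; ``sigma_eps_sd`` / ``sigma_delta_sd``:
    half-normal sds for the residual scale and the time-shift scale (years).
    The 2x2 random-effect covariance is parametrized as scales times a
    correlation: half-normal priors (``re_sd``) on the intercept/slope scales
    and an LKJ(``lkj_eta``) prior on the correlation.  Half-normal scale
    priors place no floor at zero, which keeps the joint slope/shift scale
    identified even for noise-free data.
    """

    beta_sd: float = 1.0
    gamma_sd: float = 0.5
    sigma_eps_sd: float = 0.5
    sigma_delta_sd: float = 5.0
    re_sd: tuple[float, float] = (0.1, 0.1)
    lkj_eta: float = 2.0


@dataclass(frozen=True)
class LTJMMSpec:
    """Fit settings: outcomes, covariates, sampler configuration.

    ``outcomes=None`` uses the cohort's declared joint-fit outcomes.
    ``covariates`` may be empty for the simplified (covariate-free) model used
    for age/sex association analyses.  ``iterations`` counts post-warmup draws
    per chain.
    """

    outcomes: tuple[str, ...] | None = None
    covariates: tuple[str, ...] = ("age_at_diagnosis", "sex")
    chains: int = 4
    iterations: int = 1000
    warmup: int = 1000
    seed: int = 0
    priors: Priors = field(default_factory=Priors)

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("chains must be >= 2 (split R-hat needs several)")
        if self.iterations < 1 or self.warmup < 0:
            raise ValueError("iterations must be >= 1 and warmup >= 0")
        bad = set(self.covariates) - {"age_at_diagnosis", "sex"}
        if bad:
            raise ValueError(f"unknown covariate(s) {sorted(bad)}")


@dataclass
class ModelData:
    """Flattened observation arrays plus per-(individual, outcome) sufficient
    statistics used by the blocked Gibbs sampler."""

    y: np.ndarray
    t: np.ndarray
    ind: np.ndarray  # individual index per observation
    out: np.ndarray  # outcome index per observation
    X: np.ndarray  # (n, P) design: intercept [, centered age, male]
    ids: list[str]
    outcomes: list[str]
    covariates: list[str]
    age_center: float
    # sufficient statistics, all (n, K)
    S0: np.ndarray
    S1: np.ndarray
    S2: np.ndarray
    Y0: np.ndarray
    Y1: np.ndarray
    Y2: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def K(self) -> int:
        return len(self.outcomes)

    @property
    def P(self) -> int:
        return self.X.shape[1]


def prepare_data(cohort: Cohort, spec: LTJMMSpec) -> ModelData:
    """Assemble observation arrays and sufficient statistics from a cohort.

    Requires a normalized cohort (scores on [0, 1]); raises StateError
    otherwise.  Individuals with no measurement on the selected outcomes are
    excluded.
    """
    if not cohort.normalized:
        raise StateError("LTJMM requires a normalized cohort")
    outcomes = list(spec.outcomes) if spec.outcomes else cohort.ltjmm_outcomes()
    if not outcomes:
        raise ValueError("no outcomes selected for the joint fit")
    for k in outcomes:
        s = cohort.spec(k)
        if s.scale_kind != "continuous":
            raise ValueError(f"LTJMM outcome {k!r} must be continuous")
    if len(outcomes) == 1:
        warnings.warn(
            "single-outcome fit: the time shift is confounded with the random "
            "intercept; posterior intervals for delta are unreliable",
            IdentifiabilityWarning,
            stacklevel=2,
        )

    m = cohort.measurements
    m = m[m["outcome"].isin(outcomes)]
    ids = sorted(m["individual_id"].unique())
    ind_index = {v: i for i, v in enumerate(ids)}
    out_index = {v: k for k, v in enumerate(outcomes)}

    y = m["value"].to_numpy(float)
    t = m["time_years"].to_numpy(float)
    ind = m["individual_id"].map(ind_index).to_numpy(int)
    out = m["outcome"].map(out_index).to_numpy(int)

    cov = cohort.individuals.loc[ids]
    cols = [np.ones(len(ids))]
    covariates = ["intercept"]
    age_center = float(cov["age_at_diagnosis"].mean())
    if "age_at_diagnosis" in spec.covariates:
        cols.append(cov["age_at_diagnosis"].to_numpy(float) - age_center)
        covariates.append("age_at_diagnosis")
    if "sex" in spec.covariates:
        cols.append((cov["sex"] == "male").to_numpy(float))
        covariates.append("sex")
    X = np.column_stack(cols)

    n, K = len(ids), len(outcomes)
    S0 = np.zeros((n, K))
    S1 = np.zeros((n, K))
    S2 = np.zeros((n, K))
    Y0 = np.zeros((n, K))
    Y1 = np.zeros((n, K))
    Y2 = np.zeros((n, K))
    np.add.at(S0, (ind, out), 1.0)
    np.add.at(S1, (ind, out), t)
    np.add.at(S2, (ind, out), t * t)
    np.add.at(Y0, (ind, out), y)
    np.add.at(Y1, (ind, out), y * t)
    np.add.at(Y2, (ind, out), y * y)

    return ModelData(
        y=y, t=t, ind=ind, out=out, X=X,
        ids=ids, outcomes=outcomes, covariates=covariates,
        age_center=age_center,
        S0=S0, S1=S1, S2=S2, Y0=Y0, Y1=Y1, Y2=Y2,
    )


# ---------------------------------------------------------------------------
# joint log density
# ---------------------------------------------------------------------------


def log_density(
    cohort: Cohort,
    params: dict[str, np.ndarray | float],
    spec: LTJMMSpec,
    include_priors: bool = True,
) -> float:
    """Joint log density of the LTJMM at one parameter point.

    ``params`` holds ``beta`` (K, P), ``gamma`` (K,), ``delta`` (n,),
    ``a0``/``a1`` (n, K), ``sigma_eps`` (K,), ``sigma_delta`` (scalar) and
    ``re_cov`` (K, 2, 2), with individuals/outcomes ordered as in
    :func:`prepare_data`.  Points outside the support (non-positive slopes or
    scales, non-PD covariances) return ``-inf``.  With
    ``include_priors=False`` only the Gaussian observation terms are summed.
    """
    data = prepare_data(cohort, spec)
    beta = np.atleast_2d(np.asarray(params["beta"], float))
    gamma = np.atleast_1d(np.asarray(params["gamma"], float))
    delta = np.atleast_1d(np.asarray(params["delta"], float))
    a0 = np.atleast_2d(np.asarray(params["a0"], float))
    a1 = np.atleast_2d(np.asarray(params["a1"], float))
    sigma_eps = np.atleast_1d(np.asarray(params["sigma_eps"], float))
    sigma_delta = float(params["sigma_delta"])
    re_cov = np.asarray(params["re_cov"], float).reshape(data.K, 2, 2)

    if np.any(gamma <= 0) or np.any(sigma_eps <= 0) or sigma_delta <= 0:
        return -np.inf
    for k in range(data.K):
        if np.any(np.linalg.eigvalsh(re_cov[k]) <= 0):
            return -np.inf

    mu = (
        (data.X @ beta.T)[data.ind, data.out]
        + gamma[data.out] * (data.t + delta[data.ind])
        + a0[data.ind, data.out]
        + a1[data.ind, data.out] * data.t
    )
    sd = sigma_eps[data.out]
    lp = float(np.sum(stats.norm.logpdf(data.y, mu, sd)))
    if not include_priors:
        return lp

    pr = spec.priors
    lp += float(np.sum(stats.norm.logpdf(delta, 0.0, sigma_delta)))
    for k in range(data.K):
        lp += float(
            np.sum(
                stats.multivariate_normal.logpdf(
                    np.column_stack([a0[:, k], a1[:, k]]), mean=np.zeros(2),
                    cov=re_cov[k],
                )
            )
        )
    # hyperpriors
    lp += float(np.sum(stats.norm.logpdf(beta, 0.0, pr.beta_sd)))
    lp += float(
        np.sum(stats.halfnorm.logpdf(gamma, scale=pr.gamma_sd))
    )
    lp += float(np.sum(stats.halfnorm.logpdf(sigma_eps, scale=pr.sigma_eps_sd)))
    lp += float(stats.halfnorm.logpdf(sigma_delta, scale=pr.sigma_delta_sd))
    for k in range(data.K):
        s0 = np.sqrt(re_cov[k, 0, 0])
        s1 = np.sqrt(re_cov[k, 1, 1])
        rho = re_cov[k, 0, 1] / (s0 * s1)
        lp += float(stats.halfnorm.logpdf(s0, scale=pr.re_sd[0]))
        lp += float(stats.halfnorm.logpdf(s1, scale=pr.re_sd[1]))
        lp += (pr.lkj_eta - 1.0) * np.log(max(1.0 - rho * rho, 1e-300))
    return lp
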