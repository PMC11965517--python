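"""Associations between time shifts, covariates and initial manifestations.

Outcome-level associations use the scale-appropriate coefficient: Pearson for
continuous predictions, Kendall tau-b for ordinal expected categories,
point-biserial for binary outcomes (dichotomized at 0.5 when given
probabilities).  For meta-analytic pooling every coefficient is brought to a
common scale: Kendall's tau is mapped to its Pearson equivalent through
r = sin(pi * tau / 2) (Greiner's relation) and all coefficients are Fisher
z-transformed with standard error 1/sqrt(n - 3).

Symptom domains are pooled with a three-level random-effects meta-analysis:
outcomes within a domain are pooled per cohort (DerSimonian-Laird), and the
per-cohort estimates are pooled across cohorts (DerSimonian-Laird again).
P-values and confidence intervals across domains are corrected with the
Benjamini-Hochberg procedure; CIs are recomputed at the coverage implied by
the attained BH cutoff so interval and p-value significance statements agree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "GroupComparison",
    "DomainMetaResult",
    "UndefinedCorrelationError",
    "correlate_with_shifts",
    "correlate_age",
    "compare_groups",
    "dl_pool",
    "pool_domain",
    "adjust_multiplicity",
    "subgroup_analysis",
    "coefficient_kind_for",
]

COEFFICIENT_KINDS = ("pearson", "kendall_tau_b", "point_biserial")


class UndefinedCorrelationError(ValueError):
    """Zero variance in one of the correlated vectors."""


class CovariateAdjustmentWarning(UserWarning):
    """Shifts came from a covariate-adjusted fit where age was regressed out."""


@dataclass(frozen=True)
class AssociationResult:
    outcome: str
    cohort: str
    coefficient: float
    coefficient_kind: str
    n: int
    z: float  # Fisher-z transformed effect (via Pearson equivalent for tau)
    se_z: float
    p: float

    def __post_init__(self):
        if abs(self.coefficient) > 1 + 1e-12:
            raise ValueError("|coefficient| must be <= 1")
        if self.n < 3:
            raise ValueError("n must be >= 3")


@dataclass(frozen=True)
class GroupComparison:
    grouping: str
    groups: tuple[str, str]
    test_used: str  # 't', 'welch' or 'mwu'
    statistic: float
    p: float
    cohens_d: float
    means: tuple[float, float]
    sds: tuple[float, float]
    ns: tuple[int, int]


@dataclass
class DomainMetaResult:
    domain: str
    pooled_coefficient: float
    ci_low: float
    ci_high: float
    p: float
    per_cohort: pd.DataFrame  # cohort, effect_z, se_z, n_outcomes, tau2_within
    tau2_between: float
    n_outcomes: int
    n_cohorts: int
    no_pooling: bool = False
    p_adjusted: float | None = None
    significant: bool | None = None
    ci_level: float = 0.95
    pooled_z: float = 0.0
    pooled_se_z: float = 0.0


def coefficient_kind_for(scale_kind: str) -> str:
    """Scale-appropriate correlation coefficient for an outcome kind."""
    return {
        "continuous": "pearson",
        "ordinal": "kendall_tau_b",
        "binary": "point_biserial",
    }[scale_kind]


def _fisher_z(r: float, n: int) -> tuple[float, float]:
    r = np.clip(r, -0.999999, 0.999999)
    return float(np.arctanh(r)), 1.0 / np.sqrt(n - 3.0)


def correlate_with_shifts(
    values,
    shifts,
    coefficient_kind: str,
    outcome: str = "",
    cohort: str = "",
) -> AssociationResult:
    """Correlate per-individual values with time shifts.

    Positive coefficients mean greater severity is associated with a
    later-than-average diagnosis.  Binary values given as probabilities are
    dichotomized at 0.5 for the point-biserial form (the Pearson value on the
    raw probabilities is logged for reference).
    """
    if coefficient_kind not in COEFFICIENT_KINDS:
        raise ValueError(f"unknown coefficient_kind {coefficient_kind!r}")
    v = np.asarray(values, float)
    d = np.asarray(shifts, float)
    mask = np.isfinite(v) & np.isfinite(d)
    v, d = v[mask], d[mask]
    n = len(v)
    if n < 3:
        raise UndefinedCorrelationError("need at least 3 paired observations")
    if np.ptp(v) == 0 or np.ptp(d) == 0:
        raise UndefinedCorrelationError("zero variance in values or shifts")

    if coefficient_kind == "pearson":
        r, p = stats.pearsonr(v, d)
        z, se = _fisher_z(r, n)
    elif coefficient_kind == "kendall_tau_b":
        r, p = stats.kendalltau(v, d)  # tau-b: tie-corrected
        r_eq = float(np.sin(np.pi * r / 2.0))
        z, se = _fisher_z(r_eq, n)
    else:  # point-biserial needs a 0/1 variable
        if not set(np.unique(v)) <= {0.0, 1.0}:
            r_raw = stats.pearsonr(v, d)[0]
            logger.info(
                "point_biserial: dichotomizing probabilities at 0.5 "
                "(undichotomized Pearson r=%.3f)", r_raw,
            )
            v = (v >= 0.5).astype(float)
            if np.ptp(v) == 0:
                raise UndefinedCorrelationError(
                    "dichotomization left zero variance"
                )
        r, p = stats.pointbiserialr(v, d)
        z, se = _fisher_z(r, n)
    return AssociationResult(
        outcome=outcome, cohort=cohort, coefficient=float(r),
        coefficient_kind=coefficient_kind, n=n, z=z, se_z=se, p=float(p),
    )


def correlate_age(
    shifts,
    age_at_diagnosis,
    from_covariate_adjusted_fit: bool = False,
) -> AssociationResult:
    """Pearson correlation of time shifts with predicted age at diagnosis.

    Predicted age at diagnosis = age at clinical diagnosis + shift, i.e. the
    individual's age at the common-timescale origin.  Shifts should come from
    the simplified (covariate-free) fit; passing covariate-adjusted shifts
    triggers a misuse warning because age was regressed out there.
    """
    if from_covariate_adjusted_fit:
        warnings.warn(
            "time shifts come from a covariate-adjusted fit: the age effect "
            "was partly regressed out, the correlation is attenuated",
            CovariateAdjustmentWarning,
            stacklevel=2,
        )
    d = np.asarray(_as_values(shifts), float)
    age = np.asarray(_as_values(age_at_diagnosis), float)
    pred_age = age + d
    if np.ptp(pred_age) == 0 or np.ptp(d) == 0:
        raise UndefinedCorrelationError("zero variance")
    return correlate_with_shifts(
        pred_age, d, "pearson", outcome="predicted_age_at_diagnosis"
    )


def _as_values(x):
    if isinstance(x, pd.DataFrame):
        return x["point"].to_numpy()
    if isinstance(x, pd.Series):
        return x.to_numpy()
    return np.asarray(x)


def compare_groups(shifts, labels, grouping: str = "") -> GroupComparison:
    """Two-group comparison with distribution-based test selection.

    Shapiro-Wilk normality per group at alpha = 0.05; both normal and Levene
    p >= 0.05 -> Student t; both normal but unequal variances -> Welch;
    otherwise Mann-Whitney U.  Cohen's d (pooled-sd form) is reported
    regardless of the test chosen.
    """
    d = np.asarray(_as_values(shifts), float)
    lab = np.asarray(labels)
    names = sorted(g for g in pd.unique(lab) if not pd.isna(g))
    if len(names) != 2:
        raise ValueError(f"need exactly two group labels, got {names}")
    g1 = d[lab == names[0]]
    g2 = d[lab == names[1]]
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError("both groups need n >= 3")

    def _normal(x):
        if np.ptp(x) == 0:
            return True
        return stats.shapiro(x[:5000]).pvalue >= 0.05

    normal = _normal(g1) and _normal(g2)
    if normal:
        if np.ptp(g1) == 0 and np.ptp(g2) == 0:
            equal_var = True
        else:
            equal_var = stats.levene(g1, g2).pvalue >= 0.05
        if equal_var:
            test_used = "t"
            res = stats.ttest_ind(g1, g2, equal_var=True)
        else:
            test_used = "welch"
            res = stats.ttest_ind(g1, g2, equal_var=False)
    else:
        test_used = "mwu"
        res = stats.mannwhitneyu(g1, g2, alternative="two-sided")

    n1, n2 = len(g1), len(g2)
    s1, s2 = np.std(g1, ddof=1), np.std(g2, ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    diff = float(np.mean(g1) - np.mean(g2))
    cohens_d = 0.0 if (pooled == 0 and diff == 0) else diff / pooled
    stat = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(p):  # identical constant groups
        stat, p = 0.0, 1.0
    return GroupComparison(
        grouping=grouping, groups=(str(names[0]), str(names[1])),
        test_used=test_used, statistic=stat, p=p, cohens_d=float(cohens_d),
        means=(float(np.mean(g1)), float(np.mean(g2))),
        sds=(float(s1), float(s2)), ns=(n1, n2),
    )


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------


def dl_pool(effects, variances) -> tuple[float, float, float]:
    """DerSimonian-Laird random-effects pooling.

    Returns (pooled effect, pooled se, tau^2).  A single study returns its
    own effect with tau^2 = 0.
    """
    y = np.asarray(effects, float)
    v = np.asarray(variances, float)
    if len(y) == 0:
        raise ValueError("no effects to pool")
    if len(y) == 1:
        return float(y[0]), float(np.sqrt(v[0])), 0.0
    w = 1.0 / v
    fixed = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - fixed) ** 2))
    df = len(y) - 1
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    pooled = float(np.sum(w_star * y) / np.sum(w_star))
    se = float(1.0 / np.sqrt(np.sum(w_star)))
    return pooled, se, tau2


def pool_domain(
    results: list[AssociationResult],
    domain_map: dict[str, str],
    ci_level: float = 0.95,
) -> list[DomainMetaResult]:
    """Three-level random-effects meta-analysis per symptom domain.

    Level 1: outcome-level Fisher-z effects.  Level 2: pooling across the
    outcomes of a domain within each cohort.  Level 3: pooling of the
    per-cohort estimates.  The pooled coefficient is back-transformed with
    tanh.  A domain observed as a single outcome in a single cohort is
    flagged ``no_pooling``.
    """
    unmapped = sorted({r.outcome for r in results} - set(domain_map))
    if unmapped:
        raise ValueError(f"outcomes without domain label: {unmapped[:5]}")

    by_domain: dict[str, list[AssociationResult]] = {}
    for r in results:
        by_domain.setdefault(domain_map[r.outcome], []).append(r)

    zcrit = stats.norm.ppf(0.5 + ci_level / 2.0)
    out: list[DomainMetaResult] = []
    for domain in sorted(by_domain):
        rs = by_domain[domain]
        rows = []
        for cohort in sorted({r.cohort for r in rs}):
            sub = [r for r in rs if r.cohort == cohort]
            eff, se, tau2_w = dl_pool([r.z for r in sub], [r.se_z**2 for r in sub])
            rows.append(
                {
                    "cohort": cohort,
                    "effect_z": eff,
                    "se_z": se,
                    "n_outcomes": len(sub),
                    "tau2_within": tau2_w,
                }
            )
        per_cohort = pd.DataFrame(rows)
        pooled_z, pooled_se, tau2_b = dl_pool(
            per_cohort["effect_z"], per_cohort["se_z"] ** 2
        )
        p = float(2.0 * stats.norm.sf(abs(pooled_z) / pooled_se))
        out.append(
            DomainMetaResult(
                domain=domain,
                pooled_coefficient=float(np.tanh(pooled_z)),
                ci_low=float(np.tanh(pooled_z - zcrit * pooled_se)),
                ci_high=float(np.tanh(pooled_z + zcrit * pooled_se)),
                p=p,
                per_cohort=per_cohort,
                tau2_between=tau2_b,
                n_outcomes=len(rs),
                n_cohorts=len(per_cohort),
                no_pooling=(len(rs) == 1 and len(per_cohort) == 1),
                ci_level=ci_level,
                pooled_z=float(pooled_z),
                pooled_se_z=float(pooled_se),
            )
        )
    return out


def adjust_multiplicity(
    meta_results: list[DomainMetaResult], alpha: float = 0.05
) -> list[DomainMetaResult]:
    """Benjamini-Hochberg correction across domains, with matching CIs.

    Adjusted p-values use the step-up procedure.  CIs are recomputed at level
    1 - alpha * k_star / m, where k_star is the largest BH-accepted rank (1
    when nothing is rejected, i.e. Bonferroni-width intervals), so interval
    and adjusted-p significance statements coincide.
    """
    if not meta_results:
        raise ValueError("no domains to adjust")
    m = len(meta_results)
    praw = np.array([r.p for r in meta_results])
    reject, p_adj, _, _ = multipletests(praw, alpha=alpha, method="fdr_bh")
    k_star = int(np.sum(reject)) if np.any(reject) else 1
    level = 1.0 - alpha * k_star / m
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    out = []
    for r, pa, rej in zip(meta_results, p_adj, reject):
        new = replace_meta(r)
        new.p_adjusted = float(pa)
        new.significant = bool(rej)
        new.ci_level = level
        new.ci_low = float(np.tanh(r.pooled_z - zcrit * r.pooled_se_z))
        new.ci_high = float(np.tanh(r.pooled_z + zcrit * r.pooled_se_z))
        out.append(new)
    return out


def replace_meta(r: DomainMetaResult) -> DomainMetaResult:
    return DomainMetaResult(
        domain=r.domain, pooled_coefficient=r.pooled_coefficient,
        ci_low=r.ci_low, ci_high=r.ci_high, p=r.p,
        per_cohort=r.per_cohort.copy(), tau2_between=r.tau2_between,
        n_outcomes=r.n_outcomes, n_cohorts=r.n_cohorts,
        no_pooling=r.no_pooling, p_adjusted=r.p_adjusted,
        significant=r.significant, ci_level=r.ci_level,
        pooled_z=r.pooled_z, pooled_se_z=r.pooled_se_z,
    )


# ---------------------------------------------------------------------------
# subgroup analysis
# ---------------------------------------------------------------------------

EOPD_MAX_AGE = 50.0  # early-onset PD: age at diagnosis < 50
LOPD_MIN_AGE = 60.0  # late-onset PD: age at diagnosis > 60


def subgroup_labels(individuals: pd.DataFrame, split: str) -> pd.Series:
    """Subgroup membership per individual for a given split rule.

    ``sex``: male / female.  ``median_age``: below / at-or-above the median
    age at diagnosis of the supplied (pooled) individual set.  ``eopd_lopd``:
    early-onset (< 50 y) vs late-onset (> 60 y); intermediate ages get NaN.
    """
    if split == "sex":
        return individuals["sex"].astype(object)
    age = individuals["age_at_diagnosis"].astype(float)
    if split == "median_age":
        med = float(age.median())
        return pd.Series(
            np.where(age < med, "younger", "older"), index=individuals.index,
            dtype=object,
        )
    if split == "eopd_lopd":
        lab = pd.Series(np.nan, index=individuals.index, dtype=object)
        lab[age < EOPD_MAX_AGE] = "eopd"
        lab[age > LOPD_MIN_AGE] = "lopd"
        return lab
    raise ValueError(f"unknown split {split!r}")


def subgroup_analysis(
    per_cohort_inputs: dict[str, dict],
    split: str,
    domain_map: dict[str, str],
    kinds: dict[str, str],
    min_n: int = 30,
    alpha: float = 0.05,
) -> dict[str, dict]:
    """Re-run correlate -> pool -> adjust within each subgroup.

    ``per_cohort_inputs`` maps cohort name to a dict with keys
    ``manifestation`` (individuals x outcomes frame), ``shifts`` (Series) and
    ``individuals`` (covariate frame).  The median-age split is computed on
    the pooled individual set.  Subgroups below ``min_n`` in a cohort are
    skipped for that cohort (logged); a subgroup with no usable cohort is
    reported empty.
    """
    pooled_individuals = pd.concat(
        [v["individuals"] for v in per_cohort_inputs.values()]
    )
    pooled_labels = subgroup_labels(pooled_individuals, split)
    groups = [g for g in pd.unique(pooled_labels.dropna())]

    out: dict[str, dict] = {}
    for g in groups:
        results: list[AssociationResult] = []
        skipped: list[str] = []
        for cohort_name, inp in per_cohort_inputs.items():
            labels = pooled_labels.loc[inp["individuals"].index]
            ids = labels.index[labels == g]
            if len(ids) < min_n:
                skipped.append(cohort_name)
                logger.info(
                    "subgroup %s/%s: %d individuals < %d, skipped",
                    split, g, len(ids), min_n,
                )
                continue
            mat = inp["manifestation"].loc[inp["manifestation"].index.isin(ids)]
            shifts = _shift_like(inp["shifts"]).loc[mat.index]
            for k in mat.columns:
                try:
                    results.append(
                        correlate_with_shifts(
                            mat[k], shifts, kinds[k], outcome=k, cohort=cohort_name
                        )
                    )
                except UndefinedCorrelationError:
                    continue
        if results:
            meta = adjust_multiplicity(pool_domain(results, domain_map), alpha=alpha)
        else:
            meta = []
        out[str(g)] = {"associations": results, "meta": meta, "skipped_cohorts": skipped}
    return out


def _shift_like(x) -> pd.Series:
    if isinstance(x, pd.DataFrame):
        return x["point"]
    return x
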