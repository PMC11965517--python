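"""Model-validation procedures.

Three checks mirror the study design: (1) leave-last-measurement-out
predictive R^2 of the joint latent-time fit; (2) first-visit prediction from
manifestation models refitted without the first visit, compared against a
carry-back null model (the value of the earliest visit at least one year
after the first) with a Wilcoxon signed-rank test across outcomes; (3) the
Hoehn & Yahr alignment check: the H&Y stage is held out of the joint fit, and
its rank correlation with time should strengthen on the aligned timescale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .ltjmm import LTJMMSpec, extract_time_shifts, fit, predict_measurements
from .manifestation import align_to_common_timescale, fit_manifestation_model
from .mixed_ordinal import DegenerateOutcomeError

logger = logging.getLogger(__name__)

__all__ = [
    "InsufficientDataError",
    "LeakageError",
    "ValidationReport",
    "loo_last_visit_r2",
    "first_visit_null_comparison",
    "hy_alignment_check",
]


class InsufficientDataError(ValueError):
    """Too few held-out points for a meaningful score."""


class LeakageError(ValueError):
    """The held-out outcome participates in the fit being validated."""


@dataclass
class ValidationReport:
    cohort_name: str
    loo_r2: float | None = None
    first_visit_r2: pd.DataFrame | None = None  # outcome, r2_model, r2_null
    wilcoxon_p: float | None = None
    hy_correlation_raw: float | None = None
    hy_correlation_aligned: float | None = None
    notes: dict = field(default_factory=dict)


def _pooled_r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    ss_res = float(np.sum((observed - predicted) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def loo_last_visit_r2(
    cohort: Cohort,
    spec: LTJMMSpec | None = None,
    min_series_after: int = 2,
) -> tuple[float, dict]:
    """Leave-last-measurement-out predictive R^2 of the joint fit.

    Per individual and fit outcome, the measurement with the largest time is
    excluded; the model is refitted on the remainder and the excluded values
    are predicted.  Series that would drop below ``min_series_after``
    measurements are exempted from exclusion (count reported).  Returns the
    pooled R^2 over all excluded measurements plus a per-outcome breakdown.
    """
    spec = spec or LTJMMSpec()
    outcomes = list(spec.outcomes) if spec.outcomes else cohort.ltjmm_outcomes()
    m = cohort.measurements
    fitmask = m["outcome"].isin(outcomes)
    mfit = m[fitmask]

    order = mfit.sort_values("time_years").groupby(["individual_id", "outcome"])
    last_idx = order.tail(1).index
    sizes = mfit.groupby(["individual_id", "outcome"])["time_years"].transform("size")
    droppable = mfit.loc[last_idx]
    droppable = droppable[sizes.loc[last_idx] > min_series_after]
    n_exempt = len(last_idx) - len(droppable)
    if n_exempt:
        logger.info("loo_last_visit_r2: %d series exempt from exclusion", n_exempt)
    if len(droppable) < 10:
        raise InsufficientDataError(
            f"only {len(droppable)} excluded points (< 10)"
        )

    reduced = cohort.copy()
    reduced.measurements = m.drop(index=droppable.index).reset_index(drop=True)
    post = fit(reduced, spec)
    preds = predict_measurements(post, droppable)
    obs = droppable["value"].to_numpy(float)

    per_outcome = {}
    for k in outcomes:
        mk = (droppable["outcome"] == k).to_numpy()
        if mk.sum() >= 3:
            per_outcome[k] = _pooled_r2(obs[mk], preds[mk])
    details = {
        "n_excluded": int(len(droppable)),
        "n_exempt_series": int(n_exempt),
        "per_outcome_r2": per_outcome,
        "max_rhat": post.convergence["max_rhat"],
    }
    return _pooled_r2(obs, preds), details


def first_visit_null_comparison(
    cohort: Cohort,
    shifts,
    outcomes: list[str] | None = None,
    min_individuals: int = 30,
    min_gap_years: float = 1.0,
) -> tuple[pd.DataFrame, float]:
    """First-visit prediction vs carry-back null, per outcome.

    For each outcome, manifestation models are refitted on aligned series
    without each individual's first visit, and the first-visit value is
    predicted at its aligned time.  The null model carries back the value of
    the earliest visit at least ``min_gap_years`` after the first; individuals
    without such a visit are excluded from that outcome's comparison (both
    scores use the common subset).  Returns per-outcome (r2_model, r2_null)
    and the two-sided Wilcoxon signed-rank p across outcomes.
    """
    aligned = align_to_common_timescale(cohort, shifts)
    outcomes = outcomes or list(cohort.specs)
    rows = []
    for k in outcomes:
        spec_k = cohort.spec(k)
        series = aligned[aligned["outcome"] == k].sort_values("s")
        obs_first, pred_null, eval_ids, reduced_parts = [], [], [], []
        for ind, sub in series.groupby("individual_id"):
            if len(sub) < 3:
                continue  # needs >= 2 measurements after dropping the first
            t0 = sub["time_years"].iloc[0]
            later = sub[sub["time_years"] >= t0 + min_gap_years]
            reduced_parts.append(sub.iloc[1:])
            if later.empty:
                continue
            obs_first.append((ind, sub["value"].iloc[0], sub["s"].iloc[0]))
            pred_null.append(float(later["value"].iloc[0]))
            eval_ids.append(ind)
        if len(eval_ids) < min_individuals:
            continue
        reduced = pd.concat(reduced_parts)
        try:
            model = fit_manifestation_model(reduced, spec_k.scale_kind)
        except DegenerateOutcomeError:
            continue
        if not model.converged:
            continue
        obs = np.array([v for _, v, _ in obs_first])
        pred_model = np.array(
            [model.predict_at(ind, s) for (ind, _, s) in obs_first]
        )
        rows.append(
            {
                "outcome": k,
                "r2_model": _pooled_r2(obs, pred_model),
                "r2_null": _pooled_r2(obs, np.asarray(pred_null)),
                "n_individuals": len(eval_ids),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise InsufficientDataError("no outcome with a usable comparison")
    diffs = table["r2_model"] - table["r2_null"]
    if len(table) < 2:
        wp = float("nan")  # the signed-rank test needs several outcomes
    elif np.allclose(diffs, 0):
        wp = 1.0
    else:
        wp = float(stats.wilcoxon(diffs, alternative="two-sided").pvalue)
    return table, wp


def hy_alignment_check(
    cohort: Cohort, shifts, hy_outcome: str = "hy"
) -> tuple[float, float]:
    """Kendall tau-b of H&Y stage vs raw and vs aligned time.

    The H&Y outcome must be held out of the joint fit (its spec's
    ``in_ltjmm`` flag False), otherwise :class:`LeakageError` is raised.
    When alignment works, the aligned correlation should exceed the raw one.
    """
    spec = cohort.spec(hy_outcome)
    if spec.in_ltjmm:
        raise LeakageError(
            f"{hy_outcome!r} is part of the joint fit; the alignment check "
            "requires a held-out outcome"
        )
    aligned = align_to_common_timescale(cohort, shifts)
    sub = aligned[aligned["outcome"] == hy_outcome]
    vals = sub["value"].to_numpy(float)
    if len(vals) == 0 or np.ptp(vals) == 0:
        from .association import UndefinedCorrelationError

        raise UndefinedCorrelationError(f"{hy_outcome!r}: constant or empty values")
    raw = float(stats.kendalltau(vals, sub["time_years"]).statistic)
    ali = float(stats.kendalltau(vals, sub["s"]).statistic)
    return raw, ali
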