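"""Initial clinical manifestation at the typical time of diagnosis.

Pipeline per outcome: (I) align all measurements on the common disease
timescale, s = t + delta_hat; (II) fit a mixed-effects model on the aligned
series (linear with random intercept and slope for continuous outcomes,
cumulative-logit / logistic with random intercept for ordinal / binary ones);
(III) predict each individual's outcome at s = 0, the time at which an
average individual is diagnosed.  Time shifts are treated as plug-in
constants here, mirroring the sequential two-stage design.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .cohort import Cohort
from .mixed_ordinal import DegenerateOutcomeError, OrdinalMixedModel, fit_ordinal_mixed

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentError",
    "ManifestationModel",
    "align_to_common_timescale",
    "fit_manifestation_model",
    "predict_initial_manifestation",
    "build_manifestation_matrix",
]


class AlignmentError(ValueError):
    """Some measured individuals have no time-shift estimate."""


def _shift_series(shifts) -> pd.Series:
    if isinstance(shifts, pd.DataFrame):
        return shifts["point"]
    return pd.Series(shifts)


def align_to_common_timescale(cohort: Cohort, shifts) -> pd.DataFrame:
    """Aligned long table with column ``s`` = time since diagnosis + shift.

    ``shifts`` is a Series of point estimates indexed by individual_id, or the
    time-shift frame produced by the joint fit (column ``point``).  Raises
    :class:`AlignmentError` listing individuals without a shift estimate.
    """
    pts = _shift_series(shifts)
    m = cohort.measurements
    missing = sorted(set(m["individual_id"]) - set(pts.index))
    if missing:
        raise AlignmentError(
            f"no time-shift estimate for {len(missing)} individual(s): {missing[:5]}"
        )
    out = m.copy()
    out["s"] = out["time_years"] + pts.loc[out["individual_id"]].to_numpy()
    return out.sort_values(["individual_id", "outcome", "s"]).reset_index(drop=True)


@dataclass
class ManifestationModel:
    """Per-outcome mixed model on the common disease timescale."""

    outcome: str
    scale_kind: str
    converged: bool
    n_individuals: int
    n_measurements: int
    # continuous
    fixed: tuple[float, float] | None = None  # (intercept, slope)
    ranef: pd.DataFrame | None = None  # columns u0, u1 per individual
    sigma_resid: float | None = None
    exact: bool = False  # noise-free branch used
    # ordinal / binary
    ordinal: OrdinalMixedModel | None = None
    # observed aligned-time range per individual, for extrapolation flags
    s_range: pd.DataFrame | None = None

    @property
    def individual_ids(self) -> list:
        if self.scale_kind == "continuous":
            return list(self.ranef.index)
        return list(self.ordinal.u_hat.index)

    def predict_at(self, individual_id, s: float) -> float:
        """Individual-level prediction at aligned time ``s``.

        Continuous: conditional mean from fixed + empirical-Bayes effects.
        Ordinal: probability-weighted expected category.  Binary: P(y = 1).
        """
        if self.scale_kind == "continuous":
            if individual_id not in self.ranef.index:
                raise KeyError(f"individual {individual_id!r} not in the fit")
            u0, u1 = self.ranef.loc[individual_id]
            b0, b1 = self.fixed
            return float((b0 + u0) + (b1 + u1) * s)
        if individual_id not in self.ordinal.u_hat.index:
            raise KeyError(f"individual {individual_id!r} not in the fit")
        if self.scale_kind == "binary":
            return self.ordinal.predict_probability(individual_id, s)
        return self.ordinal.expected_category(individual_id, s)

    def extrapolated_at(self, individual_id, s: float) -> bool:
        lo, hi = self.s_range.loc[individual_id]
        return not (lo <= s <= hi)


def _fit_continuous(series: pd.DataFrame) -> ManifestationModel:
    ids = series["individual_id"].to_numpy()
    s = series["s"].to_numpy(float)
    v = series["value"].to_numpy(float)
    uniq = np.unique(ids)

    # per-individual OLS; doubles as the exact branch for noise-free data
    coefs = {}
    ssr = 0.0
    for g in uniq:
        mask = ids == g
        A = np.column_stack([np.ones(mask.sum()), s[mask]])
        sol, res_, rank, _ = np.linalg.lstsq(A, v[mask], rcond=None)
        coefs[g] = sol
        ssr += float(np.sum((v[mask] - A @ sol) ** 2))
    scale = max(float(np.var(v)), 1e-12)

    if ssr / len(v) < 1e-12 * scale:
        # noise-free: the mixed model degenerates; per-individual OLS is ML
        cf = pd.DataFrame(coefs).T
        cf.columns = ["b0", "b1"]
        fixed = (float(cf["b0"].mean()), float(cf["b1"].mean()))
        ranef = cf - np.array(fixed)
        ranef.columns = ["u0", "u1"]
        ranef.index.name = "individual_id"
        return ManifestationModel(
            outcome="", scale_kind="continuous", converged=True,
            n_individuals=len(uniq), n_measurements=len(v),
            fixed=fixed, ranef=ranef, sigma_resid=0.0, exact=True,
        )

    exog = np.column_stack([np.ones(len(v)), s])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = sm.MixedLM(v, exog, groups=ids, exog_re=exog)
        res = None
        converged = False
        for method in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                cand = model.fit(reml=True, method=method, maxiter=300)
            except Exception:  # singular fits on odd data
                continue
            if res is None:
                res = cand
            if cand.converged:
                res = cand
                converged = True
                break
    if res is None:
        return ManifestationModel(
            outcome="", scale_kind="continuous", converged=False,
            n_individuals=len(uniq), n_measurements=len(v),
        )
    fe = res.fe_params
    ranef = pd.DataFrame(
        {g: re.to_numpy()[:2] for g, re in res.random_effects.items()}
    ).T
    ranef.columns = ["u0", "u1"]
    ranef.index.name = "individual_id"
    return ManifestationModel(
        outcome="", scale_kind="continuous", converged=converged,
        n_individuals=len(uniq), n_measurements=len(v),
        fixed=(float(fe[0]), float(fe[1])), ranef=ranef,
        sigma_resid=float(np.sqrt(res.scale)),
    )


def fit_manifestation_model(series: pd.DataFrame, scale_kind: str) -> ManifestationModel:
    """Fit one outcome's mixed model on aligned series.

    ``series`` needs columns ``individual_id, s, value``.  Continuous outcomes
    get a linear mixed model with correlated random intercept and slope;
    ordinal and binary outcomes get random-intercept cumulative-logit /
    logistic models (small per-individual series make random slopes on the
    latent scale unstable).  All-identical responses raise
    :class:`DegenerateOutcomeError`.
    """
    if series["value"].nunique() < 2:
        raise DegenerateOutcomeError("all response values identical")
    if scale_kind == "continuous":
        model = _fit_continuous(series)
    elif scale_kind in ("ordinal", "binary"):
        om = fit_ordinal_mixed(
            series["value"].to_numpy(float),
            series["s"].to_numpy(float),
            series["individual_id"].to_numpy(),
        )
        model = ManifestationModel(
            outcome="", scale_kind=scale_kind, converged=om.converged,
            n_individuals=om.n_individuals, n_measurements=om.n_measurements,
            ordinal=om,
        )
    else:
        raise ValueError(f"unknown scale_kind {scale_kind!r}")
    rng = series.groupby("individual_id")["s"].agg(["min", "max"])
    rng.columns = ["s_min", "s_max"]
    model.s_range = rng
    return model


def predict_initial_manifestation(model: ManifestationModel, individual_id) -> float:
    """Predicted outcome at s = 0, the typical time of diagnosis."""
    return model.predict_at(individual_id, 0.0)


def build_manifestation_matrix(
    cohort: Cohort,
    shifts,
    outcomes: list[str] | None = None,
    min_individuals: int = 30,
    min_measurements: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Individuals x outcomes matrix of predicted values at s = 0.

    Applies align -> fit -> predict per outcome.  Returns (matrix,
    extrapolation flags, log).  Outcomes whose model does not converge, or
    that fail the inclusion minima, appear in the log and are absent from the
    matrix.  Matrix entries are missing where an individual lacks a usable
    series for that outcome.
    """
    aligned = align_to_common_timescale(cohort, shifts)
    outcomes = outcomes or list(cohort.specs)
    values: dict[str, pd.Series] = {}
    extrap: dict[str, pd.Series] = {}
    log: dict[str, dict] = {}

    for k in outcomes:
        spec = cohort.spec(k)
        series = aligned[aligned["outcome"] == k]
        sizes = series.groupby("individual_id").size()
        keep = sizes.index[sizes >= min_measurements]
        series = series[series["individual_id"].isin(keep)]
        entry: dict = {"n_individuals": int(len(keep)), "n_measurements": int(len(series))}
        if len(keep) < min_individuals:
            entry["status"] = "excluded_too_few_individuals"
            log[k] = entry
            continue
        try:
            model = fit_manifestation_model(series, spec.scale_kind)
        except DegenerateOutcomeError:
            entry["status"] = "excluded_degenerate"
            log[k] = entry
            continue
        model.outcome = k
        if not model.converged:
            entry["status"] = "excluded_nonconvergent"
            log[k] = entry
            continue
        preds = {}
        flags = {}
        for ind in model.individual_ids:
            preds[ind] = model.predict_at(ind, 0.0)
            flags[ind] = model.extrapolated_at(ind, 0.0)
        values[k] = pd.Series(preds)
        extrap[k] = pd.Series(flags)
        entry["status"] = "ok"
        entry["extrapolated_fraction"] = float(np.mean(list(flags.values())))
        log[k] = entry

    matrix = pd.DataFrame(values).reindex(cohort.individuals.index)
    flags = pd.DataFrame(extrap).reindex(cohort.individuals.index)
    matrix.index.name = flags.index.name = "individual_id"
    return matrix, flags, log
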