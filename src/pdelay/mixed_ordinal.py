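"""Random-intercept cumulative-logit (ordinal) and logistic (binary) models.

Maximum marginal likelihood with Gauss-Hermite quadrature over the Gaussian
random intercept.  The cumulative-logit model for categories c = 0..C-1 is

    P(y_ij <= c | u_i) = logistic(theta_c - (b * s_ij + u_i)),   u_i ~ N(0, s_u^2)

with strictly increasing cutpoints theta.  The binary logistic model is the
single-cutpoint case (fixed intercept = -theta_0).  Per-individual random
intercepts are recovered as empirical-Bayes posterior means on the quadrature
grid, which is what the downstream per-individual predictions use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

__all__ = ["OrdinalMixedModel", "fit_ordinal_mixed", "DegenerateOutcomeError"]


class DegenerateOutcomeError(ValueError):
    """All response values identical: no model can be fitted."""


@dataclass
class OrdinalMixedModel:
    """Fitted cumulative-logit / logistic random-intercept model."""

    categories: np.ndarray  # original category values, ascending
    thetas: np.ndarray  # cutpoints, len C-1
    slope: float  # coefficient on aligned time s
    sigma_u: float
    u_hat: pd.Series  # empirical-Bayes random intercept per individual
    converged: bool
    loglik: float
    n_individuals: int
    n_measurements: int

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def category_probs(self, individual_id, s: float) -> np.ndarray:
        """Per-category probabilities at aligned time ``s``."""
        u = float(self.u_hat.loc[individual_id])
        eta = self.slope * s + u
        cum = expit(self.thetas - eta)
        cum = np.concatenate([[0.0], np.clip(cum, 0.0, 1.0), [1.0]])
        cum = np.maximum.accumulate(cum)
        return np.diff(cum)

    def expected_category(self, individual_id, s: float) -> float:
        """Probability-weighted mean category on the original coding."""
        return float(self.category_probs(individual_id, s) @ self.categories)

    def modal_category(self, individual_id, s: float) -> float:
        return float(self.categories[np.argmax(self.category_probs(individual_id, s))])

    def predict_probability(self, individual_id, s: float) -> float:
        """Binary models: P(y = 1) at aligned time ``s``."""
        if self.n_categories != 2:
            raise ValueError("predict_probability requires a binary model")
        u = float(self.u_hat.loc[individual_id])
        return float(expit(self.slope * s + u - self.thetas[0]))


def _pack(thetas: np.ndarray, slope: float, log_sigma_u: float) -> np.ndarray:
    head = [thetas[0]]
    if len(thetas) > 1:
        head += list(np.log(np.diff(thetas)))
    return np.array(head + [slope, log_sigma_u])


def _unpack(x: np.ndarray, n_cut: int):
    t0 = x[0]
    thetas = np.empty(n_cut)
    thetas[0] = t0
    if n_cut > 1:
        thetas[1:] = t0 + np.cumsum(np.exp(x[1 : n_cut]))
    return thetas, float(x[n_cut]), float(x[n_cut + 1])


def fit_ordinal_mixed(
    values: np.ndarray,
    s: np.ndarray,
    groups: np.ndarray,
    n_quad: int = 25,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> OrdinalMixedModel:
    """Fit by maximum marginal likelihood (Gauss-Hermite, BFGS).

    ``values`` may be any numeric category coding; observed unique values are
    used as the ordered categories.
    """
    values = np.asarray(values, float)
    s = np.asarray(s, float)
    groups = np.asarray(groups)
    categories = np.unique(values)
    if len(categories) < 2:
        raise DegenerateOutcomeError("all response values are identical")
    codes = np.searchsorted(categories, values)
    n_cut = len(categories) - 1

    uniq, grp_idx = np.unique(groups, return_inverse=True)
    n_grp = len(uniq)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)  # N(0,1) weights
    wts = weights / np.sqrt(2.0 * np.pi)

    # starting values from marginal category frequencies
    freq = np.bincount(codes, minlength=len(categories)) / len(codes)
    cum = np.clip(np.cumsum(freq)[:-1], 1e-4, 1 - 1e-4)
    thetas0 = logit(cum)
    x0 = _pack(thetas0, 0.0, np.log(1.0))

    big = 30.0

    def negloglik(x: np.ndarray) -> float:
        thetas, slope, log_su = _unpack(x, n_cut)
        su = np.exp(log_su)
        eta = slope * s  # (m,)
        u = su * nodes  # (Q,)
        z = eta[:, None] + u[None, :]  # (m, Q)
        upper = np.where(
            codes[:, None] < n_cut, thetas[np.minimum(codes, n_cut - 1)][:, None] - z, big
        )
        lower = np.where(codes[:, None] > 0, thetas[np.maximum(codes - 1, 0)][:, None] - z, -big)
        p = expit(upper) - expit(lower)
        logp = np.log(np.clip(p, 1e-300, None))
        # per-group sum of log p at each node
        grp_log = np.zeros((n_grp, len(nodes)))
        np.add.at(grp_log, grp_idx, logp)
        mx = grp_log.max(axis=1, keepdims=True)
        lik = np.exp(grp_log - mx) @ wts
        return -float(np.sum(mx[:, 0] + np.log(np.clip(lik, 1e-300, None))))

    res = minimize(
        negloglik, x0, method="BFGS", options={"gtol": tol, "maxiter": max_iter}
    )
    # BFGS with finite-difference gradients often stops on "precision loss"
    # at an adequate optimum; accept when the gradient is numerically small
    # relative to the objective scale
    grad_ok = res.jac is not None and float(np.max(np.abs(res.jac))) < 1e-2 * max(
        1.0, abs(float(res.fun))
    ) ** 0.5
    converged = bool(res.success or grad_ok)
    thetas, slope, log_su = _unpack(res.x, n_cut)
    su = float(np.exp(log_su))

    # empirical-Bayes posterior mean of u per group on the quadrature grid
    u = su * nodes
    z = slope * s[:, None] + u[None, :]
    upper = np.where(
        codes[:, None] < n_cut, thetas[np.minimum(codes, n_cut - 1)][:, None] - z, big
    )
    lower = np.where(codes[:, None] > 0, thetas[np.maximum(codes - 1, 0)][:, None] - z, -big)
    logp = np.log(np.clip(expit(upper) - expit(lower), 1e-300, None))
    grp_log = np.zeros((n_grp, len(nodes)))
    np.add.at(grp_log, grp_idx, logp)
    grp_log = grp_log + np.log(np.clip(wts, 1e-300, None))[None, :]
    mx = grp_log.max(axis=1, keepdims=True)
    w = np.exp(grp_log - mx)
    u_hat = (w @ u) / w.sum(axis=1)

    return OrdinalMixedModel(
        categories=categories,
        thetas=thetas,
        slope=slope,
        sigma_u=su,
        u_hat=pd.Series(u_hat, index=pd.Index(uniq, name="individual_id")),
        converged=converged,
        loglik=-float(res.fun),
        n_individuals=n_grp,
        n_measurements=len(values),
    )
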