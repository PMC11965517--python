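"""MCMC convergence diagnostics: split R-hat and effective sample size.

``compute_rhat`` implements the split-chain potential scale reduction factor.
The plain variant is the classical between/within variance ratio on half-split
chains; the rank-normalized variant (default for fit gating) transforms draws
to normal scores first and takes the worse of the bulk and folded (median
absolute deviation) statistics, which is sensitive to both location and scale
disagreement between chains.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

__all__ = ["compute_rhat", "split_chains", "effective_sample_size"]


def split_chains(chains: np.ndarray) -> np.ndarray:
    """Split each chain in half: (C, N, ...) -> (2C, N//2, ...)."""
    chains = np.asarray(chains, float)
    c, n = chains.shape[:2]
    if n < 4:
        raise ValueError("need at least 4 draws per chain to split")
    half = n // 2
    first = chains[:, :half]
    second = chains[:, half : 2 * half]
    return np.concatenate([first, second], axis=0)


def _rhat_basic(chains: np.ndarray) -> np.ndarray:
    """Classical split R-hat on pre-split chains (C, N, ...)."""
    c, n = chains.shape[:2]
    means = chains.mean(axis=1)
    within = chains.var(axis=1, ddof=1).mean(axis=0)
    between = n * means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * within + between / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / within)
    # zero within-chain variance: identical/constant chains converge by
    # convention, disagreeing constant chains diverge
    flat = within == 0
    if np.any(flat):
        rhat = np.asarray(rhat)
        disagree = between > 0
        rhat[flat & ~disagree] = 1.0
        rhat[flat & disagree] = np.inf
    # values below 1 are estimator noise and carry no convergence signal
    return np.maximum(rhat, 1.0)


def _rank_normalize(chains: np.ndarray) -> np.ndarray:
    c, n = chains.shape[:2]
    flat = chains.reshape(c * n, -1)
    r = rankdata(flat, axis=0)
    z = ndtri((r - 3.0 / 8.0) / (c * n + 0.25))
    return z.reshape(chains.shape)


def compute_rhat(chains: np.ndarray, rank_normalized: bool = True) -> np.ndarray:
    """Split R-hat for draws shaped (n_chains, n_draws, ...).

    Returns an array of the trailing shape (a scalar for 2-D input).  Requires
    at least 2 chains and 4 draws per chain.  Constant identical chains return
    exactly 1.0 by convention.
    """
    chains = np.asarray(chains, float)
    if chains.ndim < 2:
        raise ValueError("chains must be at least 2-D: (n_chains, n_draws)")
    if chains.shape[0] < 2:
        raise ValueError("need at least 2 chains")
    scalar = chains.ndim == 2
    if scalar:
        chains = chains[..., None]

    split = split_chains(chains)
    if not rank_normalized:
        out = _rhat_basic(split)
        return float(out[0]) if scalar else out

    const = np.ptp(chains.reshape(-1, chains.shape[-1]), axis=0) == 0
    bulk = _rhat_basic(_rank_normalize(split))
    med = np.median(chains.reshape(-1, chains.shape[-1]), axis=0)
    folded = np.abs(chains - med)
    fold = _rhat_basic(_rank_normalize(split_chains(folded)))
    out = np.maximum(bulk, fold)
    out = np.where(const, 1.0, out)
    return float(out[0]) if scalar else out


def _autocovariance(x: np.ndarray) -> np.ndarray:
    """Per-chain autocovariance via FFT; x shaped (C, N, m)."""
    c, n, m = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, n=nfft, axis=1)
    acov = np.fft.irfft(f * np.conjugate(f), n=nfft, axis=1)[:, :n]
    return acov / n


def effective_sample_size(chains: np.ndarray) -> np.ndarray:
    """Bulk effective sample size (Geyer initial monotone sequence).

    Input shaped (n_chains, n_draws, ...); returns the trailing shape.
    """
    chains = np.asarray(chains, float)
    scalar = chains.ndim == 2
    if scalar:
        chains = chains[..., None]
    shape = chains.shape[2:]
    c, n = chains.shape[:2]
    x = chains.reshape(c, n, -1)
    m = x.shape[-1]

    acov = _autocovariance(x)
    chain_var = acov[:, 0] * n / (n - 1.0)
    mean_var = chain_var.mean(axis=0)
    var_plus = mean_var * (n - 1.0) / n
    if c > 1:
        var_plus = var_plus + x.mean(axis=1).var(axis=0, ddof=1)

    ess = np.empty(m)
    for j in range(m):
        if var_plus[j] == 0:
            ess[j] = c * n
            continue
        rho = 1.0 - (mean_var[j] - acov[:, :, j].mean(axis=0)) / var_plus[j]
        # Geyer: sum consecutive lag pairs while positive, forced monotone
        tau_sum = 0.0
        prev = np.inf
        for tlag in range((n - 1) // 2):
            p = rho[2 * tlag] + rho[2 * tlag + 1]
            if p <= 0:
                break
            p = min(p, prev)
            prev = p
            tau_sum += p
        tau = max(2.0 * tau_sum - 1.0, 1.0 / np.log10(c * n + 10.0))
        ess[j] = c * n / tau
    out = ess.reshape(shape) if shape else ess
    return float(out[0]) if scalar else out.reshape(shape)
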