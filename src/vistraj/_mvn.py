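"""Multivariate-normal helpers for data with missing waves.

Subjects are grouped by their pattern of observed waves so that the
covariance factorisation is done once per pattern, not once per subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class Pattern:
    """One missingness pattern: which waves are observed, for which rows."""

    obs: np.ndarray  # indices of observed waves, shape (p_obs,)
    rows: np.ndarray  # row indices into the data matrix
    y: np.ndarray  # observed values, shape (n_rows, p_obs)
    # sufficient statistics of the observed block
    n: int
    ybar: np.ndarray
    s: np.ndarray  # ML covariance (divisor n)


def pattern_groups(y: np.ndarray) -> list[Pattern]:
    """Group rows of ``y`` (NaN = missing) by missingness pattern."""
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y)
    patterns: list[Pattern] = []
    # lexicographic key per row
    keys = mask @ (1 << np.arange(y.shape[1]))
    for key in np.unique(keys):
        rows = np.flatnonzero(keys == key)
        obs = np.flatnonzero(mask[rows[0]])
        if obs.size == 0:
            continue
        block = y[np.ix_(rows, obs)]
        ybar = block.mean(axis=0)
        d = block - ybar
        s = d.T @ d / len(rows)
        patterns.append(
            Pattern(obs=obs, rows=rows, y=block, n=len(rows), ybar=ybar, s=s)
        )
    return patterns


def gaussian_loglik_pattern(pat: Pattern, mu: np.ndarray, sigma: np.ndarray) -> float:
    """Gaussian log-likelihood of one pattern from its sufficient statistics.

    ``mu``/``sigma`` are the full-wave moments; the observed sub-block is
    taken here.
    """
    mu_o = mu[pat.obs]
    sig_o = sigma[np.ix_(pat.obs, pat.obs)]
    p = len(pat.obs)
    cf = cho_factor(sig_o, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    d = pat.ybar - mu_o
    quad = float(d @ cho_solve(cf, d))
    trace = float(np.trace(cho_solve(cf, pat.s)))
    return -0.5 * pat.n * (p * LOG_2PI + logdet + trace + quad)


def gaussian_loglik(patterns: list[Pattern], mu: np.ndarray, sigma: np.ndarray) -> float:
    return float(sum(gaussian_loglik_pattern(p, mu, sigma) for p in patterns))


def saturated_mvn_fit(
    y: np.ndarray, max_iter: int = 500, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, float]:
    """ML mean/covariance of a multivariate normal with missing entries.

    EM over the missing coordinates; reduces to the ML moments in one pass
    when the data are complete. Returns ``(mu, sigma, loglik)``.
    """
    y = np.asarray(y, dtype=float)
    n, p = y.shape
    patterns = pattern_groups(y)
    if len(patterns) == 1 and len(patterns[0].obs) == p:
        pat = patterns[0]
        ll = gaussian_loglik(patterns, pat.ybar, pat.s)
        return pat.ybar, pat.s, ll

    # moment start from available entries
    mu = np.nanmean(y, axis=0)
    dev = np.where(np.isnan(y), 0.0, y - mu)
    counts = (~np.isnan(y)).astype(float)
    sigma = (dev.T @ dev) / np.maximum(counts.T @ counts, 1.0)
    sigma += np.eye(p) * 1e-6

    ll_old = -np.inf
    for _ in range(max_iter):
        # E-step: expected sufficient statistics
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        for pat in patterns:
            obs = pat.obs
            mis = np.setdiff1d(np.arange(p), obs)
            cf = cho_factor(sigma[np.ix_(obs, obs)], lower=True)
            d = pat.y - mu[obs]  # (n_r, p_obs)
            ey = np.zeros((pat.n, p))
            ey[:, obs] = pat.y
            if mis.size:
                b = cho_solve(cf, sigma[np.ix_(obs, mis)])  # (p_obs, p_mis)
                ey[:, mis] = mu[mis] + d @ b
                cond = sigma[np.ix_(mis, mis)] - sigma[np.ix_(mis, obs)] @ b
            s1 += ey.sum(axis=0)
            s2 += ey.T @ ey
            if mis.size:
                s2[np.ix_(mis, mis)] += pat.n * cond
        mu = s1 / n
        sigma = s2 / n - np.outer(mu, mu)
        sigma = 0.5 * (sigma + sigma.T)
        ll = gaussian_loglik(patterns, mu, sigma)
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    return mu, sigma, gaussian_loglik(patterns, mu, sigma)
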