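"""Single-class latent linear growth-curve model (LGCM).

The model for a subject's wave-level scores y_i (length p) is

    y_i = Lambda eta_i + eps_i,   eta_i ~ N(alpha, Psi),  eps_i ~ N(0, Theta)

with Lambda = [1 | t] (intercept loadings fixed at one, slope loadings at
the wave time scores), giving implied moments mu = Lambda alpha and
Sigma = Lambda Psi Lambda' + Theta. Estimation is by maximum likelihood;
with ``allow_partial`` the likelihood is evaluated over each subject's
observed waves (full-information ML), otherwise on complete cases.

Fit indices follow the usual SEM conventions. The ML discrepancy is

    F = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p + (ybar-mu)' Sigma^-1 (ybar-mu)

with test statistic T = (n-1) F; the baseline (independence) model frees
the wave means and variances and fixes all covariances to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from vistraj import _mvn
from vistraj.errors import EstimationError

__all__ = [
    "GrowthDesign",
    "LgcmParams",
    "FitIndices",
    "LgcmFit",
    "implied_moments",
    "fit_lgcm",
    "fit_indices",
    "n_moments",
    "lgcm_free_params",
]


@dataclass(frozen=True)
class GrowthDesign:
    """Loading structure of the linear growth model."""

    time_scores: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)

    @property
    def n_waves(self) -> int:
        return len(self.time_scores)

    @property
    def loading_matrix(self) -> np.ndarray:
        t = np.asarray(self.time_scores, dtype=float)
        return np.column_stack([np.ones_like(t), t])


@dataclass
class LgcmParams:
    """Growth-factor means, factor covariance, residual variances."""

    alpha: np.ndarray  # (2,)
    psi: np.ndarray  # (2, 2)
    theta: np.ndarray  # (p,) diagonal residual variances

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)


@dataclass
class FitIndices:
    chi_square: float
    df: int
    chi_df_ratio: float
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    n_used: int


@dataclass
class LgcmFit:
    params: LgcmParams
    loglik: float
    indices: FitIndices
    converged: bool
    n_used: int


def implied_moments(params: LgcmParams, design: GrowthDesign) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance matrix."""
    lam = design.loading_matrix
    mu = lam @ params.alpha
    sigma = lam @ params.psi @ lam.T + np.diag(params.theta)
    return mu, 0.5 * (sigma + sigma.T)


def n_moments(p: int) -> int:
    """Number of observed moments: p means + p(p+1)/2 (co)variances."""
    return p * (p + 3) // 2


def lgcm_free_params(p: int, equal_theta: bool = False) -> int:
    """2 factor means + 3 factor (co)variances + residual variances."""
    return 2 + 3 + (1 if equal_theta else p)


def _pack_start(alpha, psi, theta, equal_theta):
    # Psi via log-Cholesky, theta via log
    psi = np.asarray(psi, float) + 1e-8 * np.eye(2)
    chol = np.linalg.cholesky(psi)
    th = np.asarray(theta, float)
    th_part = [np.log(max(th.mean(), 1e-6))] if equal_theta else list(np.log(np.maximum(th, 1e-6)))
    return np.array(
        [alpha[0], alpha[1], np.log(chol[0, 0]), chol[1, 0], np.log(chol[1, 1]), *th_part]
    )


def _unpack(x, p, equal_theta):
    alpha = x[:2]
    chol = np.array([[np.exp(x[2]), 0.0], [x[3], np.exp(x[4])]])
    psi = chol @ chol.T
    theta = np.full(p, np.exp(x[5])) if equal_theta else np.exp(x[5 : 5 + p])
    return LgcmParams(alpha=alpha, psi=psi, theta=theta)


def _ols_growth_estimates(y: np.ndarray, design: GrowthDesign) -> tuple[np.ndarray, float]:
    """Per-subject OLS (intercept, slope), NaN-aware; rows need >= 2 waves.

    Returns the (n, 2) estimate matrix and a pooled residual-variance
    estimate for use as a starting value.
    """
    lam = design.loading_matrix
    out = np.full((y.shape[0], 2), np.nan)
    resid_var = []
    for pat in _mvn.pattern_groups(y):
        if len(pat.obs) < 2:
            continue
        lp = lam[pat.obs]
        b, *_ = np.linalg.lstsq(lp, pat.y.T, rcond=None)
        out[pat.rows] = b.T
        r = pat.y - b.T @ lp.T
        if len(pat.obs) > 2:
            resid_var.append(np.sum(r**2) / (pat.n * (len(pat.obs) - 2)))
    pooled = float(np.mean(resid_var)) if resid_var else 0.1
    return out, pooled


def fit_lgcm(
    data,
    design: GrowthDesign | None = None,
    allow_partial: bool = False,
    min_waves: int = 3,
    equal_theta: bool = False,
    compute_indices: bool = True,
) -> LgcmFit:
    """Maximum-likelihood fit of the linear growth-curve model.

    ``data`` is an (n, p) array of wave scores (NaN = missing), a
    :class:`~vistraj.synth.CohortTable`, or a DataFrame with vision columns.
    With ``allow_partial`` subjects contribute their observed waves
    (full-information likelihood), subject to at least ``min_waves``
    observations; otherwise only complete cases are used.
    """
    design = design or GrowthDesign()
    y = _as_matrix(data, design.n_waves)
    p = design.n_waves
    if allow_partial:
        y = y[(~np.isnan(y)).sum(axis=1) >= min_waves]
    else:
        y = y[~np.isnan(y).any(axis=1)]
    n = y.shape[0]
    if n <= lgcm_free_params(p, equal_theta):
        raise EstimationError(f"{n} subjects < number of free parameters")

    patterns = _mvn.pattern_groups(y)
    lam = design.loading_matrix

    def negll(x):
        params = _unpack(x, p, equal_theta)
        mu, sigma = implied_moments(params, design)
        try:
            return -_mvn.gaussian_loglik(patterns, mu, sigma)
        except np.linalg.LinAlgError:
            return 1e12

    # moment-based start values from per-subject OLS growth estimates
    b, pooled_resid = _ols_growth_estimates(y, design)
    b = b[~np.isnan(b).any(axis=1)]
    alpha0 = b.mean(axis=0)
    theta0 = max(pooled_resid, 1e-3)
    psi0 = np.cov(b.T) - theta0 * np.linalg.inv(lam.T @ lam)
    ev, evec = np.linalg.eigh(0.5 * (psi0 + psi0.T))
    psi0 = evec @ np.diag(np.maximum(ev, 1e-4)) @ evec.T
    starts = [
        _pack_start(alpha0, psi0, np.full(p, theta0), equal_theta),
        _pack_start(alpha0, np.diag([0.25, 0.02]), np.full(p, 0.2), equal_theta),
    ]

    best = None
    for x0 in starts:
        res = minimize(negll, x0, method="L-BFGS-B", options={"maxiter": 2000, "ftol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    params = _unpack(best.x, p, equal_theta)
    loglik = -float(best.fun)
    converged = bool(best.success)
    if not converged:
        warnings.warn(f"LGCM optimiser did not report convergence: {best.message}")

    indices = None
    if compute_indices:
        indices = _indices_for_fit(patterns, y, params, design, loglik, equal_theta)
    return LgcmFit(params=params, loglik=loglik, indices=indices, converged=converged, n_used=n)


def _as_matrix(data, n_waves: int) -> np.ndarray:
    from vistraj.synth import CohortTable  # local import to avoid cycle

    if isinstance(data, CohortTable):
        return data.vision_matrix()
    if hasattr(data, "columns"):
        cols = [f"vision_w{w + 1}" for w in range(n_waves)]
        return data[cols].to_numpy(dtype=float)
    return np.asarray(data, dtype=float)


def _indices_for_fit(patterns, y, params, design, loglik, equal_theta) -> FitIndices:
    p = design.n_waves
    n = y.shape[0]
    complete = len(patterns) == 1 and len(patterns[0].obs) == p
    if complete:
        ybar, s = patterns[0].ybar, patterns[0].s
        ll_sat = _mvn.gaussian_loglik(patterns, ybar, s)
    else:
        ybar, s, ll_sat = _mvn.saturated_mvn_fit(y)
    mu, sigma = implied_moments(params, design)
    f_model = 2.0 * (ll_sat - loglik) / n
    t_model = (n - 1) * f_model
    df_model = n_moments(p) - lgcm_free_params(p, equal_theta)

    # independence baseline: free means/variances, zero covariances
    if complete:
        sd = np.diag(s)
        f_base = float(np.sum(np.log(sd)) - np.linalg.slogdet(s)[1])
    else:
        mu_b = np.array([np.nanmean(y[:, j]) for j in range(p)])
        var_b = np.array([np.nanvar(y[:, j]) for j in range(p)])
        ll_base = _mvn.gaussian_loglik(patterns, mu_b, np.diag(var_b))
        f_base = 2.0 * (ll_sat - ll_base) / n
    t_base = (n - 1) * f_base
    df_base = n_moments(p) - 2 * p
    return fit_indices(t_model, df_model, t_base, df_base, s, sigma, n)


def fit_indices(
    t_model: float,
    df_model: int,
    t_base: float,
    df_base: int,
    sample_cov: np.ndarray,
    implied_cov: np.ndarray,
    n: int,
) -> FitIndices:
    """CFI / TLI / RMSEA / SRMR from test statistics and covariance residuals.

    CFI   = 1 - max(T_M - df_M, 0) / max(T_B - df_B, T_M - df_M, 0)
    TLI   = ((T_B/df_B) - (T_M/df_M)) / ((T_B/df_B) - 1)
    RMSEA = sqrt(max(T_M - df_M, 0) / (df_M (n-1)))
    SRMR  = RMS of standardised covariance residuals, lower triangle
            including the diagonal (covariance-only convention).
    """
    if df_model <= 0 or df_base <= 0:
        raise EstimationError("fit indices require positive degrees of freedom")
    if df_base <= df_model:
        raise EstimationError("baseline model must have more df than the target model")
    num = max(t_model - df_model, 0.0)
    den = max(t_base - df_base, t_model - df_model, 0.0)
    cfi = 1.0 if den == 0.0 else 1.0 - num / den
    rb = t_base / df_base
    rm = t_model / df_model
    tli = 1.0 if rb == 1.0 else (rb - rm) / (rb - 1.0)
    rmsea = float(np.sqrt(num / (df_model * (n - 1))))
    s = np.asarray(sample_cov, float)
    sig = np.asarray(implied_cov, float)
    d = np.sqrt(np.diag(s))
    std_resid = (s - sig) / np.outer(d, d)
    tri = np.tril_indices_from(std_resid)
    srmr = float(np.sqrt(np.mean(std_resid[tri] ** 2)))
    return FitIndices(
        chi_square=float(t_model),
        df=int(df_model),
        chi_df_ratio=float(t_model / df_model),
        cfi=float(np.clip(cfi, 0.0, 1.0)),
        tli=float(np.clip(tli, 0.0, 1.0)),
        rmsea=rmsea,
        srmr=srmr,
        n_used=int(n),
    )
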