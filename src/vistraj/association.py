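"""Class-membership and distal-outcome regressions.

Covers the last two analysis steps: multivariable logistic regression of
trajectory-class membership on screened baseline predictors (odds ratios
with Wald 95% CIs), linear/logistic models for distal outcomes (an
unadjusted class contrast, "model 1", and a covariate-adjusted "model 2"),
a restricted-cubic-spline dose-response analysis for continuous exposures,
and chained-equation multiple imputation with Rubin pooling.

Reference levels for the packaged categorical predictors are the field
conventions of the emulated analysis: male sex, rural birthplace, living
with family, non-professional occupation, no formal qualifications, poor
economic status, not married, never-smoker, rare drinking, rare exercise,
low fruit/vegetable frequency, disease absent. Binary 0/1 predictors enter
as-is (0 is the reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression

from vistraj.errors import DataError, EstimationError

__all__ = [
    "RegressionResult",
    "SplineSpec",
    "DoseResponse",
    "logistic_fit",
    "linear_fit",
    "rcs_basis",
    "rcs_dose_response",
    "rubin_pool",
    "impute_and_pool",
    "REFERENCE_LEVELS",
]

Z95 = 1.96  # large-sample normal quantile used for all 95% CIs

REFERENCE_LEVELS = {
    "residence": "family",
    "smoking": "never",
    "drinking": "rare",
    "exercise": "rare",
}


@dataclass
class RegressionResult:
    """Coefficient table of a fitted linear or logistic model."""

    table: pd.DataFrame  # term, coef, se, ci_low, ci_high, p_value [, odds_ratio...]
    model_kind: str  # "linear" | "logistic"
    n_used: int
    covariate_tag: str = ""
    loglik: float | None = None
    pooled_m: int | None = None  # number of imputations when Rubin-pooled

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "coef"])

    def se(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "se"])


@dataclass
class SplineSpec:
    """Restricted-cubic-spline configuration for dose-response models."""

    knots: tuple[float, ...] | None = None
    knot_quantiles: tuple[float, ...] = (0.05, 0.35, 0.65, 0.95)
    reference: float | None = None  # curve centering value (e.g. BMI 21.0)

    def resolve_knots(self, x: np.ndarray) -> np.ndarray:
        if self.knots is not None:
            knots = np.asarray(self.knots, dtype=float)
        else:
            knots = np.quantile(x[~np.isnan(x)], self.knot_quantiles)
        if len(knots) < 3 or np.any(np.diff(knots) <= 0):
            raise DataError("spline needs >= 3 strictly increasing knots")
        return knots


# ---------------------------------------------------------------------------
# design construction


def build_design(
    df: pd.DataFrame,
    terms: list[str],
    reference_levels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Numeric design columns for ``terms``, dummy-coding categoricals.

    Categorical levels are coded against the reference level from
    ``reference_levels`` (falling back to :data:`REFERENCE_LEVELS`, then to
    the first observed level); dummy columns are named ``var[level]``.
    """
    refs = {**REFERENCE_LEVELS, **(reference_levels or {})}
    cols = {}
    for term in terms:
        if term not in df.columns:
            raise DataError(f"term {term!r} not in data")
        col = df[term]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            levels = list(pd.unique(col.dropna()))
            ref = refs.get(term, levels[0])
            if ref not in levels:
                raise DataError(f"reference level {ref!r} absent for {term!r}")
            for lvl in levels:
                if lvl == ref:
                    continue
                cols[f"{term}[{lvl}]"] = (col == lvl).astype(float)
        else:
            cols[term] = pd.to_numeric(col).astype(float)
    return pd.DataFrame(cols, index=df.index)


def _check_full_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # flag columns whose removal restores rank
        bad = []
        for j in range(x.shape[1]):
            keep = [i for i in range(x.shape[1]) if i != j]
            if np.linalg.matrix_rank(x[:, keep]) == rank:
                bad.append(names[j])
        raise EstimationError(f"singular design; collinear terms: {bad or names}")


def _result_table(names, beta, se, pvals, logistic: bool) -> pd.DataFrame:
    ci_low = beta - Z95 * se
    ci_high = beta + Z95 * se
    tab = pd.DataFrame(
        {"term": names, "coef": beta, "se": se, "ci_low": ci_low,
         "ci_high": ci_high, "p_value": pvals}
    )
    if logistic:
        tab["odds_ratio"] = np.exp(beta)
        tab["or_ci_low"] = np.exp(ci_low)
        tab["or_ci_high"] = np.exp(ci_high)
    return tab


def logistic_fit(
    df: pd.DataFrame,
    outcome: str,
    terms: list[str],
    covariates: list[str] = (),
    reference_levels: dict[str, str] | None = None,
    covariate_tag: str = "",
) -> RegressionResult:
    """ML logistic regression (IRLS) with Wald standard errors.

    ``outcome`` must be a 0/1 column with both levels present; odds ratios
    are reported per term alongside the coefficients.
    """
    all_terms = list(terms) + [t for t in covariates if t not in terms]
    design = build_design(df, all_terms, reference_levels)
    y = pd.to_numeric(df[outcome])
    keep = design.notna().all(axis=1) & y.notna()
    design, y = design[keep], y[keep]
    yv = y.to_numpy(dtype=float)
    if set(np.unique(yv)) != {0.0, 1.0}:
        raise DataError(f"outcome {outcome!r} must be binary with both levels present")
    x = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    names = ["const", *design.columns]
    _check_full_rank(x, names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(yv, x).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises on perfect separation
            raise EstimationError(f"logistic fit failed: {exc}") from exc
    beta = np.asarray(res.params)
    if not np.all(np.isfinite(res.bse)) or np.any(np.abs(beta[1:]) > 15):
        worst = names[1:][int(np.argmax(np.abs(beta[1:])))]
        raise EstimationError(f"quasi-complete separation; offending term: {worst}")
    tab = _result_table(names, beta, np.asarray(res.bse), np.asarray(res.pvalues), True)
    return RegressionResult(
        table=tab, model_kind="logistic", n_used=int(keep.sum()),
        covariate_tag=covariate_tag, loglik=float(res.llf),
    )


def linear_fit(
    df: pd.DataFrame,
    outcome: str,
    terms: list[str],
    covariates: list[str] = (),
    reference_levels: dict[str, str] | None = None,
    covariate_tag: str = "",
) -> RegressionResult:
    """Ordinary least squares with Wald (normal) 95% CIs."""
    all_terms = list(terms) + [t for t in covariates if t not in terms]
    design = build_design(df, all_terms, reference_levels)
    y = pd.to_numeric(df[outcome])
    keep = design.notna().all(axis=1) & y.notna()
    design, y = design[keep], y[keep]
    x = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    names = ["const", *design.columns]
    _check_full_rank(x, names)
    res = sm.OLS(y.to_numpy(dtype=float), x).fit()
    tab = _result_table(names, np.asarray(res.params), np.asarray(res.bse),
                        np.asarray(res.pvalues), False)
    return RegressionResult(
        table=tab, model_kind="linear", n_used=int(keep.sum()),
        covariate_tag=covariate_tag, loglik=float(res.llf),
    )


# ---------------------------------------------------------------------------
# restricted cubic splines


def rcs_basis(x, knots, normalize: bool = True) -> np.ndarray:
    """Restricted-cubic (natural) truncated-power basis.

    Returns an (n, K-1) matrix: the linear column x followed by K-2
    nonlinear terms

        X_j = (x-t_j)+^3 - (x-t_{K-1})+^3 (t_K-t_j)/(t_K-t_{K-1})
                         + (x-t_K)+^3 (t_{K-1}-t_j)/(t_K-t_{K-1}),

    scaled by 1/(t_K - t_1)^2 when ``normalize`` (keeps columns on the
    scale of x). The implied function is linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    if len(t) < 3 or np.any(np.diff(t) <= 0):
        raise DataError("spline needs >= 3 strictly increasing knots")
    k = len(t)
    scale = (t[-1] - t[0]) ** 2 if normalize else 1.0

    def cube(v):
        return np.maximum(v, 0.0) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[k - 2]) * (t[-1] - t[j]) / (t[-1] - t[k - 2])
            + cube(x - t[-1]) * (t[k - 2] - t[j]) / (t[-1] - t[k - 2])
        )
        cols.append(term / scale)
    return np.column_stack(cols)


@dataclass
class DoseResponse:
    curve: pd.DataFrame  # exposure grid, log-odds relative to reference, CI
    p_nonlinearity: float
    knots: np.ndarray
    reference: float
    result: RegressionResult = field(repr=False, default=None)


def rcs_dose_response(
    df: pd.DataFrame,
    exposure: str,
    outcome: str,
    covariates: list[str] = (),
    spec: SplineSpec | None = None,
    reference_levels: dict[str, str] | None = None,
    n_grid: int = 100,
) -> DoseResponse:
    """Spline dose-response of class membership on a continuous exposure.

    Fits a logistic model with the restricted-cubic basis of ``exposure``
    plus ``covariates``; the nonlinearity p-value is a Wald test that all
    nonlinear spline coefficients are zero; the curve is the fitted
    log-odds relative to the reference exposure value (0 there by
    construction).
    """
    spec = spec or SplineSpec()
    xall = pd.to_numeric(df[exposure]).to_numpy(dtype=float)
    knots = spec.resolve_knots(xall)
    lo, hi = np.nanmin(xall), np.nanmax(xall)
    if knots[0] < lo or knots[-1] > hi:
        raise DataError("knots outside the observed exposure range")
    basis = rcs_basis(xall, knots)
    base_names = [exposure] + [f"{exposure}_rcs{j + 1}" for j in range(basis.shape[1] - 1)]
    work = df.copy()
    for name, col in zip(base_names, basis.T):
        work[name] = col
    res = logistic_fit(work, outcome, base_names, covariates, reference_levels,
                       covariate_tag="spline")
    tab = res.table.set_index("term")
    beta = tab.loc[base_names, "coef"].to_numpy()

    # Wald test: nonlinear coefficients jointly zero
    sm_res = _refit_statsmodels(work, outcome, base_names, covariates, reference_levels)
    names = ["const"] + list(
        build_design(work, base_names + [c for c in covariates if c not in base_names],
                     reference_levels).columns
    )
    constraint = np.zeros((len(base_names) - 1, len(names)))
    for i, nm in enumerate(base_names[1:]):
        constraint[i, names.index(nm)] = 1.0
    wald = sm_res.wald_test(constraint, scalar=True)
    p_nonlin = float(wald.pvalue)

    ref = spec.reference if spec.reference is not None else float(np.nanmedian(xall))
    grid = np.union1d(np.linspace(lo, hi, n_grid), [ref])
    gb = rcs_basis(grid, knots)
    rb = rcs_basis(np.array([ref]), knots)
    rel = (gb - rb) @ beta
    cov = np.asarray(sm_res.cov_params())
    idx = [names.index(nm) for nm in base_names]
    sub = cov[np.ix_(idx, idx)]
    se = np.sqrt(np.einsum("ij,jk,ik->i", gb - rb, sub, gb - rb))
    curve = pd.DataFrame(
        {exposure: grid, "log_odds": rel,
         "ci_low": rel - Z95 * se, "ci_high": rel + Z95 * se}
    )
    return DoseResponse(curve=curve, p_nonlinearity=p_nonlin, knots=knots,
                        reference=ref, result=res)


def _refit_statsmodels(df, outcome, terms, covariates, reference_levels):
    all_terms = list(terms) + [t for t in covariates if t not in terms]
    design = build_design(df, all_terms, reference_levels)
    y = pd.to_numeric(df[outcome])
    keep = design.notna().all(axis=1) & y.notna()
    x = sm.add_constant(design[keep].to_numpy(dtype=float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.Logit(y[keep].to_numpy(dtype=float), x).fit(disp=0, maxiter=200)


# ---------------------------------------------------------------------------
# multiple imputation


def rubin_pool(estimates, variances) -> pd.DataFrame:
    """Rubin's rules for m imputed fits of the same coefficient vector.

    ``estimates``/``variances`` are (m, k) arrays. Returns Qbar, the
    within (Wbar) and between (B) components, and total variance
    T = Wbar + (1 + 1/m) B.
    """
    q = np.atleast_2d(np.asarray(estimates, dtype=float))
    w = np.atleast_2d(np.asarray(variances, dtype=float))
    m = q.shape[0]
    qbar = q.mean(axis=0)
    wbar = w.mean(axis=0)
    between = q.var(axis=0, ddof=1) if m > 1 else np.zeros_like(qbar)
    total = wbar + (1.0 + 1.0 / m) * between
    return pd.DataFrame(
        {"estimate": qbar, "within_var": wbar, "between_var": between, "total_var": total}
    )


def _impute_one(sub: pd.DataFrame, rng: np.random.Generator, cycles: int) -> pd.DataFrame:
    """One chained-equation completion of ``sub`` (model variables only)."""
    work = sub.copy()
    miss_cols = [c for c in work.columns if work[c].isna().any()]
    for c in miss_cols:
        obs = work[c].dropna()
        if obs.empty:
            raise DataError(f"variable {c!r} has no observed values")
        fill = obs.sample(n=work[c].isna().sum(), replace=True, random_state=rng.integers(2**31))
        work.loc[work[c].isna(), c] = fill.to_numpy()
    for _ in range(cycles):
        for c in miss_cols:
            mask = sub[c].isna().to_numpy()
            others = [v for v in work.columns if v != c]
            x = build_design(work, others)
            xv = x.to_numpy(dtype=float)
            col = sub[c]
            categorical = isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object
            yv = col if categorical else pd.to_numeric(col)
            if categorical or set(pd.unique(yv.dropna())) <= {0, 1}:
                clf = LogisticRegression(max_iter=500, C=1e4)
                clf.fit(xv[~mask], np.asarray(yv[~mask]))
                proba = clf.predict_proba(xv[mask])
                draws = [clf.classes_[rng.choice(len(clf.classes_), p=p)] for p in proba]
                work.loc[mask, c] = draws
            else:
                yobs = yv[~mask].to_numpy(dtype=float)
                xa = np.column_stack([np.ones((~mask).sum()), xv[~mask]])
                beta, *_ = np.linalg.lstsq(xa, yobs, rcond=None)
                resid = yobs - xa @ beta
                dof = max(len(yobs) - xa.shape[1], 1)
                sd = np.sqrt(resid @ resid / dof)
                xm = np.column_stack([np.ones(mask.sum()), xv[mask]])
                work.loc[mask, c] = xm @ beta + rng.standard_normal(mask.sum()) * sd
    return work


def impute_and_pool(
    df: pd.DataFrame,
    kind: str,
    outcome: str,
    terms: list[str],
    covariates: list[str] = (),
    m: int = 5,
    seed: int | None = None,
    cycles: int = 5,
    reference_levels: dict[str, str] | None = None,
    covariate_tag: str = "",
) -> RegressionResult:
    """Chained-equation MI for missing model variables, Rubin-pooled fit.

    Continuous variables are imputed by linear regression plus normal
    noise, binary/categorical variables by (multinomial) logistic draws,
    over ``cycles`` sweeps and ``m`` completed datasets. With no missing
    values this reduces to a single direct fit (between-imputation
    variance zero).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if kind not in ("linear", "logistic"):
        raise ValueError("kind must be 'linear' or 'logistic'")
    fitter = linear_fit if kind == "linear" else logistic_fit
    model_vars = [outcome] + [t for t in list(terms) + list(covariates) if t != outcome]
    sub = df[model_vars]
    if not sub.isna().any().any():
        return fitter(df, outcome, terms, covariates, reference_levels, covariate_tag)
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    fits = []
    for child in ss.spawn(m):
        rng = np.random.default_rng(child)
        completed = _impute_one(sub, rng, cycles)
        frame = df.copy()
        frame[model_vars] = completed
        fits.append(fitter(frame, outcome, terms, covariates, reference_levels, covariate_tag))
    names = fits[0].table["term"].tolist()
    est = np.array([f.table["coef"].to_numpy() for f in fits])
    var = np.array([f.table["se"].to_numpy() ** 2 for f in fits])
    pooled = rubin_pool(est, var)
    se = np.sqrt(pooled["total_var"].to_numpy())
    beta = pooled["estimate"].to_numpy()
    pvals = 2.0 * norm.sf(np.abs(beta) / np.where(se > 0, se, np.inf))
    tab = _result_table(names, beta, se, pvals, kind == "logistic")
    return RegressionResult(
        table=tab, model_kind=kind, n_used=fits[0].n_used,
        covariate_tag=covariate_tag, pooled_m=m,
    )
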