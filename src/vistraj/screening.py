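"""Univariate screening of baseline predictors against trajectory class.

Categorical predictors are tested with the uncorrected Pearson chi-square
(the convention that reproduces published class-by-level tables exactly);
continuous predictors with the Mann-Whitney rank-sum test, reported as a
tie-corrected normal-approximation Z alongside median (IQR) summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, norm, rankdata

from vistraj.errors import DataError

__all__ = ["ScreeningRow", "chi_square_test", "mann_whitney_test", "build_screening_table"]


@dataclass
class ScreeningRow:
    variable: str
    kind: str  # "categorical" | "continuous"
    summary: dict[str, str]  # per-class display summary
    statistic: float
    statistic_kind: str  # "chi2" | "Z"
    df: int | None
    p_value: float
    selected: bool


def chi_square_test(observed) -> tuple[float, int, float]:
    """Pearson chi-square on an RxC count table, no continuity correction."""
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DataError("need at least a 2x2 count table")
    if np.any(obs < 0):
        raise DataError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0):
        raise DataError(f"empty row category at index {int(np.argmin(rows))}")
    if np.any(cols == 0):
        raise DataError(f"empty column category at index {int(np.argmin(cols))}")
    chi2, p, df, _ = chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)


def mann_whitney_test(x, y) -> tuple[float, float, float]:
    """Mann-Whitney U with tie-corrected normal approximation.

    Returns (U, Z, two-sided p); U counts wins of ``x`` over ``y`` via
    midranks. If all pooled values are identical, Z is undefined and
    (U, nan, nan) is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise DataError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    if counts.max() == n:
        return float(u), float("nan"), float("nan")
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1.0))
    sigma = np.sqrt(n1 * n2 / 12.0 * ((n + 1.0) - tie_term))
    z = (u - n1 * n2 / 2.0) / sigma
    p = 2.0 * norm.sf(abs(z))
    return float(u), float(z), float(p)


def _is_categorical(series: pd.Series) -> bool:
    if isinstance(series.dtype, pd.CategoricalDtype) or series.dtype == object:
        return True
    vals = series.dropna().unique()
    return len(vals) <= 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}


def build_screening_table(
    cohort: pd.DataFrame,
    labels,
    predictors: list[str] | None = None,
    threshold: float = 0.05,
    kinds: dict[str, str] | None = None,
) -> list[ScreeningRow]:
    """Screen each predictor against the class labels.

    ``labels`` is a per-subject class assignment (exactly two distinct
    classes required). ``kinds`` may force "categorical"/"continuous" per
    variable; otherwise object/categorical/0-1 columns are treated as
    categorical and the rest as continuous. A row is ``selected`` when its
    p-value falls below ``threshold``.
    """
    labels = np.asarray(labels)
    classes = pd.unique(labels)
    if len(classes) < 2:
        raise DataError("screening needs at least two classes present")
    if len(classes) != 2:
        raise DataError("screening is defined for exactly two classes")
    classes = sorted(classes, key=str)
    predictors = predictors or [c for c in cohort.columns if c not in ("id", "true_class")]
    kinds = kinds or {}
    out: list[ScreeningRow] = []
    for name in predictors:
        if name not in cohort.columns:
            raise DataError(f"predictor {name!r} not in cohort")
        col = cohort[name]
        kind = kinds.get(name) or ("categorical" if _is_categorical(col) else "continuous")
        if kind == "categorical":
            tab = pd.crosstab(col, labels)
            stat, df, p = chi_square_test(tab.to_numpy())
            summary = {}
            for ci in classes:
                total = tab[ci].sum()
                summary[str(ci)] = "; ".join(
                    f"{lvl}: {tab.loc[lvl, ci]} ({100 * tab.loc[lvl, ci] / total:.1f}%)"
                    for lvl in tab.index
                )
            out.append(
                ScreeningRow(name, "categorical", summary, stat, "chi2", df, p, p < threshold)
            )
        elif kind == "continuous":
            groups = [pd.to_numeric(col[labels == ci]).to_numpy() for ci in classes]
            _, z, p = mann_whitney_test(groups[0], groups[1])
            summary = {}
            for ci, g in zip(classes, groups):
                g = g[~np.isnan(g)]
                iqr = np.percentile(g, 75) - np.percentile(g, 25)
                summary[str(ci)] = f"{np.median(g):.1f} ({iqr:.1f})"
            out.append(
                ScreeningRow(
                    name, "continuous", summary, z, "Z", None, p,
                    bool(p < threshold) if np.isfinite(p) else False,
                )
            )
        else:
            raise DataError(f"unknown predictor kind {kind!r} for {name}")
    return out


def screening_frame(rows: list[ScreeningRow]) -> pd.DataFrame:
    """Flatten screening rows into a tidy table."""
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "kind": [r.kind for r in rows],
            "statistic": [r.statistic for r in rows],
            "statistic_kind": [r.statistic_kind for r in rows],
            "df": [r.df for r in rows],
            "p_value": [r.p_value for r in rows],
            "selected": [r.selected for r in rows],
        }
    )
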