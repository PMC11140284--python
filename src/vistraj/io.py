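"""Cohort CSV input/output.

Wide format: one row per subject, columns ``id, vision_w1..vision_wP``,
then predictors/outcomes, optional ``true_class``; empty fields are
missing. Long format (``id, wave, vision``) is pivoted to wide on read.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from vistraj.errors import DataError
from vistraj.synth import CohortTable

__all__ = ["read_cohort_csv", "write_cohort_csv"]


def read_cohort_csv(
    path,
    n_waves: int = 4,
    predictor_names: list[str] | None = None,
    outcome_names: list[str] | None = None,
) -> CohortTable:
    """Read a cohort table, accepting wide or long vision layout.

    Raises :class:`DataError` naming any missing required column or
    duplicated subject id; vision values outside [1, 4] produce a warning
    with the offending row count (continuous synthetic scores without
    censoring legitimately exceed the instrument range slightly).
    """
    df = pd.read_csv(path)
    if {"wave", "vision"} <= set(df.columns):
        if "id" not in df.columns:
            raise DataError("long format requires column 'id'")
        wide = df.pivot(index="id", columns="wave", values="vision")
        wide.columns = [f"vision_w{int(w)}" for w in wide.columns]
        extra = df.drop(columns=["wave", "vision"]).drop_duplicates("id").set_index("id")
        df = wide.join(extra).reset_index()
    vision_cols = [f"vision_w{w + 1}" for w in range(n_waves)]
    for col in ["id", *vision_cols]:
        if col not in df.columns:
            raise DataError(f"required column {col!r} missing")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].unique()[:5]
        raise DataError(f"duplicate subject ids: {list(dups)}")
    y = df[vision_cols].to_numpy(dtype=float)
    bad = np.nansum((y < 1.0) | (y > 4.0))
    if bad:
        warnings.warn(f"{int(bad)} vision values outside the 1-4 instrument range")
    known = {"id", "true_class", *vision_cols}
    others = [c for c in df.columns if c not in known]
    return CohortTable(
        data=df,
        n_waves=n_waves,
        predictor_names=predictor_names if predictor_names is not None else others,
        outcome_names=outcome_names or [],
    )


def write_cohort_csv(table: CohortTable, path, include_true_class: bool = True) -> None:
    df = table.data
    if not include_true_class:
        df = df.drop(columns=["true_class"], errors="ignore")
    df.to_csv(path, index=False, na_rep="")
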