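#!/usr/bin/env python
"""Step 3: univariate screening of baseline predictors.

Tests every baseline predictor against the modal trajectory labels from
03_enumerate_classes.py: uncorrected Pearson chi-square for categorical
variables, Mann-Whitney Z for continuous ones. Variables significant at
0.05 feed the multivariable model in script 05.
"""

import sys
from pathlib import Path

import pandas as pd

from vistraj import io, screening

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = io.read_cohort_csv(RESULTS / "cohort.csv")
    labels = pd.read_csv(RESULTS / "labels.csv")["label"].to_numpy()
    outcome_like = {"cognition", "adl", "iadl", "depression", "anxiety", "fall"}
    predictors = [p for p in cohort.predictor_names if p not in outcome_like]
    rows = screening.build_screening_table(
        cohort.estimation_view(), labels, predictors, threshold=0.05
    )
    frame = screening.screening_frame(rows)
    print(frame.to_string(index=False))
    kept = frame.loc[frame["selected"], "variable"].tolist()
    print(f"\n{len(kept)} of {len(rows)} predictors pass screening: {', '.join(kept)}")
    frame.to_csv(RESULTS / "screening.csv", index=False, float_format="%.6g")
    print(f"wrote {RESULTS / 'screening.csv'}")


if __name__ == "__main__":
    sys.exit(main())
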