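#!/usr/bin/env python
"""Step 5: distal consequences of the visual trajectories.

For each distal outcome (cognition, ADL, IADL, depression, anxiety as
linear models; fall risk as logistic), contrasts the high-baseline-decline
class against the low-baseline-improvement class: model 1 unadjusted,
model 2 adjusted for sex, birthplace, residence, occupation, education,
economic status and marital status.
"""

import sys
from pathlib import Path

import pandas as pd

from vistraj import association, io
from vistraj.errors import EstimationError
from vistraj.pipeline import MODEL2_DEFAULT

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = io.read_cohort_csv(RESULTS / "cohort.csv")
    labels = pd.read_csv(RESULTS / "labels.csv")["label"].to_numpy()
    df = cohort.estimation_view().copy()
    df["class_high"] = (labels == "high-baseline decline").astype(int)
    model2 = [c for c in MODEL2_DEFAULT if c in df.columns]

    outcomes = [
        ("cognition", "linear"), ("adl", "linear"), ("iadl", "linear"),
        ("depression", "linear"), ("anxiety", "linear"), ("fall", "logistic"),
    ]
    frames = []
    for outcome, kind in outcomes:
        fitter = association.linear_fit if kind == "linear" else association.logistic_fit
        line = [outcome]
        for tag, covs in (("model1", []), ("model2", model2)):
            try:
                res = fitter(df, outcome, ["class_high"], covs, covariate_tag=tag)
            except EstimationError as exc:
                # sparse categorical cells can separate a logistic model in
                # a given synthetic draw; report and move on
                line.append(f"not estimable ({exc})")
                continue
            row = res.table.set_index("term").loc["class_high"]
            if kind == "logistic":
                line.append(
                    f"OR {row['odds_ratio']:.3f} ({row['or_ci_low']:.3f}, "
                    f"{row['or_ci_high']:.3f}) p={row['p_value']:.3g}"
                )
            else:
                line.append(
                    f"beta {row['coef']:.3f} ({row['ci_low']:.3f}, "
                    f"{row['ci_high']:.3f}) p={row['p_value']:.3g}"
                )
            frame = res.table.copy()
            frame.insert(0, "model", tag)
            frame.insert(0, "outcome", outcome)
            frame.insert(2, "kind", kind)
            frames.append(frame)
        print(f"{line[0]:<12} {line[1]}   |   adjusted: {line[2]}")
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(RESULTS / "outcomes.csv", index=False, float_format="%.6g")
    print(f"wrote {RESULTS / 'outcomes.csv'}")


if __name__ == "__main__":
    sys.exit(main())
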