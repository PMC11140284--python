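#!/usr/bin/env python
"""Step 2: how many trajectory classes?

Fits growth mixtures with 1-4 classes to the working cohort and applies
the selection rule: information criteria reported per K, both the
(approximate) LMR test and the bootstrap LRT significant at 0.05 at every
accepted step, and every modal class at least 5% of the sample. Writes
the per-K table and the class-mean trajectory table for the selected
solution.
"""

import sys
from pathlib import Path

import pandas as pd

from vistraj import growth, io, mixture

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20240531


def main() -> None:
    cohort = io.read_cohort_csv(RESULTS / "cohort.csv")
    y = cohort.vision_matrix()
    report = mixture.enumerate_classes(
        y, k_max=4, b=50, seed=SEED, n_starts=30, n_starts_boot=3, max_iter=400
    )
    print(report.table.to_string(index=False))
    for line in report.selection_trace:
        print(" ", line)
    print(f"selected K = {report.selected_k}")
    report.table.to_csv(RESULTS / "enumeration.csv", index=False, float_format="%.6g")

    fit = report.fits[report.selected_k]
    labels = mixture.assign_labels(fit)
    lam = growth.GrowthDesign().loading_matrix
    rows = []
    for j, lbl in enumerate(labels.labels):
        mu = lam @ fit.params.alpha[j]
        print(
            f"{lbl}: share {labels.shares[lbl]:.3f}, "
            f"intercept {fit.params.alpha[j, 0]:.3f}, slope {fit.params.alpha[j, 1]:.3f}"
        )
        for w, m in enumerate(mu):
            rows.append({"class": lbl, "wave": w + 1, "implied_mean": m,
                         "share": labels.shares[lbl]})
    pd.DataFrame(rows).to_csv(RESULTS / "trajectories.csv", index=False, float_format="%.6g")
    pd.DataFrame({"id": cohort.data["id"], "label": labels.named}).to_csv(
        RESULTS / "labels.csv", index=False
    )
    print(f"wrote {RESULTS / 'enumeration.csv'}, trajectories.csv, labels.csv")


if __name__ == "__main__":
    sys.exit(main())
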