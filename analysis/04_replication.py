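#!/usr/bin/env python
"""Replicate-level behaviour of the stepwise model and the ROC analysis.

Regenerates 100 cohorts from the default parameterisation and asks: how
often do the ALPS index and the WML grade survive backward elimination,
and how discriminative is each predictor on average? Writes
results/replication.tsv.
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from dtialps.pipeline import STEPWISE_CANDIDATES
from dtialps.stats import SeparationError, backward_stepwise, roc_auc
from dtialps.synthetic import TABLE1_COHORT, make_cohort

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    warnings.filterwarnings("ignore")
    retention = {t: 0 for t in STEPWISE_CANDIDATES}
    aucs = {"alps_index": [], "wml_sum": []}
    failed = 0
    reps = 100
    for seed in range(reps):
        df = make_cohort(TABLE1_COHORT, seed=40_000 + seed)
        y = (df.group == "CI").astype(float)
        for col in aucs:
            aucs[col].append(roc_auc(df[col], y, direction="auto").auc)
        try:
            fit, _ = backward_stepwise(df[STEPWISE_CANDIDATES], y, alpha_remove=0.10)
        except SeparationError:
            failed += 1
            continue
        for t in fit.terms:
            retention[t] += 1

    rows = [
        {"term": t, "retention_rate": retention[t] / reps,
         "mean_auroc_alone": float(np.mean(aucs[t])) if t in aucs else np.nan}
        for t in STEPWISE_CANDIDATES
    ]
    df_out = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df_out.to_csv(OUT / "replication.tsv", sep="\t", index=False)
    print(df_out.round(3).to_string(index=False))
    print(f"\n{failed} replicate(s) aborted on quasi-separation.")
    print("The ALPS index and the WML grade dominate retention (both are "
          "coupled to the outcome by construction). Education and the CMB "
          "count retain at intermediate rates — both carry real signal in "
          "the generator (the MoCA cutoff depends on education; CMB counts "
          "differ between groups) — while the purely null risk factors sit "
          "near the 0.10 removal threshold.")
    return 0


if __name__ == "__main__":
    sys.exit(main())
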