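#!/usr/bin/env python
"""Repeated stratified cross-validation of the LDA + logistic stages to
quantify overfitting of the score.

Reads results/features.csv and results/cohort_scored.csv; writes
results/cv.json and results/cv_folds.csv; prints the resubstitution
AUC, the mean cross-validated AUC and the optimism (their difference).
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from cadscore import read_cohort_csv, repeated_cv
from cadscore.features import FEATURE_NAMES


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--folds", type=int, default=10)
    ap.add_argument("--repeats", type=int, default=50)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    feats = pd.read_csv(args.results / "features.csv")
    cohort = read_cohort_csv(args.results / "cohort_scored.csv")
    X = feats[list(FEATURE_NAMES)].to_numpy()
    y = feats["significant_cad"].to_numpy(int)
    C = np.column_stack([cohort["age"].to_numpy(float),
                         (cohort["sex"] == "male").to_numpy(float),
                         cohort["hypertension"].to_numpy(float)])

    res = repeated_cv(X, C, y, folds=args.folds, repeats=args.repeats, seed=args.seed)
    (args.results / "cv.json").write_text(json.dumps(res.as_dict(), indent=1))
    res.fold_table().to_csv(args.results / "cv_folds.csv", index=False)
    print(f"resubstitution AUC      {res.resubstitution_auc:.3f}")
    print(f"mean CV AUC ({args.repeats}x{args.folds}-fold) {res.mean_cv_auc:.3f}")
    print(f"optimism                {res.optimism:.3f}")


if __name__ == "__main__":
    main()
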