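#!/usr/bin/env python
"""Simulate heart-sound recordings for the cohort, run QC and
segmentation, extract the eight acoustic features, fit the LDA +
logistic fusion and calibrate the 0-99 scale.

Reads results/cohort.csv; writes results/features.csv (8 named feature
columns + label per included patient), results/model.json and
results/cohort_scored.csv; prints exclusion accounting and the
calibration check (fraction of significant-CAD patients scoring > 20,
anchored at 90 %).
"""

import argparse
from pathlib import Path

import pandas as pd

from cadscore import CohortConfig, read_cohort_csv, roc_auc, write_cohort_csv
from cadscore.features import FEATURE_NAMES
from cadscore.pipeline import extract_cohort_features, fit_cad_score_model


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = read_cohort_csv(args.results / "cohort.csv")
    cfg = CohortConfig(n=len(cohort), seed=args.seed)
    included, X, exclusions = extract_cohort_features(cohort, cfg)
    print(f"included {len(included)}/{len(cohort)}; exclusions: {exclusions}")

    model, scores = fit_cad_score_model(X, included)
    included = included.copy()
    included["cad_score"] = scores

    feats = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    feats["significant_cad"] = (included["disease_level"] == "significant_cad").astype(int)
    feats.insert(0, "patient_id", included["patient_id"].to_numpy())
    feats.to_csv(args.results / "features.csv", index=False)
    model.to_json(args.results / "model.json")
    write_cohort_csv(included, args.results / "cohort_scored.csv")

    y = feats["significant_cad"].to_numpy(bool)
    frac = (scores[y] > model.threshold).mean()
    auc = roc_auc(scores.astype(float), y).auc
    print(f"calibration: {100 * frac:.1f}% of significant-CAD patients score > {model.threshold}")
    print(f"training AUC of the CAD-score (significant-CAD vs other): {auc:.3f}")


if __name__ == "__main__":
    main()
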