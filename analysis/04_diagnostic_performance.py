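#!/usr/bin/env python
"""Diagnostic performance of the CAD-score threshold, both on the
simulated cohort and straight from the published pooled 2x2 counts.

Reads results/cohort_scored.csv; writes results/diagnostics.json;
prints the metric blocks (sens/spec/PPV/NPV with exact 95 % CIs,
likelihood ratios, post-test probability after a negative score).
"""

import argparse
import json
from pathlib import Path

from cadscore import confusion_matrix, read_cohort_csv, roc_auc
from cadscore.pipeline import evaluate_from_counts


def show(label, rep):
    print(f"\n{label}")
    for k in ("sensitivity", "specificity", "ppv", "npv"):
        lo, hi = rep[k]["ci_pct"]
        print(f"  {k:<12} {rep[k]['pct']:5.1f}%  ({lo}-{hi}%)")
    print(f"  PLR {rep['plr']}  NLR {rep['nlr']}  prevalence {rep['prevalence_pct']}%")
    print(f"  post-test P(CAD | score <= 20) = {rep['post_test_probability_negative_pct']}%")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = read_cohort_csv(args.results / "cohort_scored.csv")
    truth = (cohort["disease_level"] == "significant_cad").to_numpy()
    pred = cohort["cad_score"].to_numpy(float) > 20
    cm = confusion_matrix(pred, truth)
    sim = evaluate_from_counts(cm.tp, cm.fp, cm.tn, cm.fn)
    sim["auc"] = round(roc_auc(cohort["cad_score"].to_numpy(float), truth).auc, 3)

    published = evaluate_from_counts(tp=188, fn=24, tn=844, fp=1189)

    (args.results / "diagnostics.json").write_text(
        json.dumps({"simulated": sim, "published_counts": published}, indent=1))
    show(f"simulated cohort (n={cm.total}), AUC {sim['auc']}", sim)
    show("published pooled counts (TP 188, FN 24, TN 844, FP 1189)", published)


if __name__ == "__main__":
    main()
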