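"""End-to-end study simulation: cohort -> recordings -> QC/segmentation
-> features -> score fitting & calibration -> PTP reclassification ->
diagnostic evaluation -> cross-validation.

Also provides the counts-only evaluation path: every 2x2-derived
statistic (sensitivity/specificity/PPV/NPV with exact CIs, likelihood
ratios, Bayesian post-test probabilities) computed directly from
supplied confusion-matrix counts, through the same statistics code the
simulation path uses.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import score as sc
from .crossval import repeated_cv
from .processing import QCThresholds, SegmentationError, quality_check, segment_heart_sounds
from .reclassification import (PTPModel, compute_ptp, ptp_band, reclassification_table,
                               net_reclassification_index)
from .stats import (confusion_matrix, delong_paired_test, diagnostic_summary,
                    post_test_probability, roc_auc)
from .synthetic import CohortConfig, generate_cohort, simulate_pcg, write_cohort_csv

log = logging.getLogger("cadscore")


@dataclass
class RunConfig:
    """Serializable configuration of a full analysis run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    ptp: PTPModel = field(default_factory=PTPModel.default)
    qc: QCThresholds = field(default_factory=QCThresholds)
    cv_folds: int = 10
    cv_repeats: int = 50
    calibration_min_cases: int = 20
    run_cv: bool = True
    exclude_asymptomatic_from_reclassification: bool = True
    output_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            c = dict(d["cohort"])
            for k in ("prevalence", "age_shift_by_level", "female_frac_by_level",
                      "hypertension_frac_by_level", "diabetes_frac_by_level",
                      "heart_rate_range", "murmur_amp_by_level", "murmur_band"):
                if k in c:
                    c[k] = tuple(c[k])
            if "symptom_mix_by_level" in c:
                c["symptom_mix_by_level"] = tuple(tuple(row) for row in c["symptom_mix_by_level"])
            d["cohort"] = CohortConfig(**c)
        if "ptp" in d:
            d["ptp"] = PTPModel(**d["ptp"])
        if "qc" in d:
            d["qc"] = QCThresholds(**d["qc"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def extract_cohort_features(cohort: pd.DataFrame, config: CohortConfig,
                            qc: QCThresholds | None = None) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Simulate, QC, segment and featurise every patient.

    Returns (included cohort rows, feature matrix aligned with them,
    exclusion counts by reason).
    """
    qc = qc or QCThresholds()
    rows, fdicts = [], []
    exclusions = {"arrhythmia": 0, "noisy_or_weak": 0, "too_short": 0, "segmentation_failure": 0}
    for i, row in enumerate(cohort.itertuples(index=False)):
        rec = simulate_pcg(cohort.iloc[i], config, patient_index=i)
        verdict = quality_check(rec.pretest if rec.pretest is not None else rec, qc)
        if not verdict.passed:
            exclusions[verdict.reason] += 1
            continue
        try:
            seg = segment_heart_sounds(rec)
            fdicts.append(feat.extract_features(rec, seg))
        except (SegmentationError, ValueError):
            exclusions["segmentation_failure"] += 1
            continue
        rows.append(i)
    included = cohort.iloc[rows].reset_index(drop=True)
    X = feat.feature_matrix(fdicts) if fdicts else np.empty((0, len(feat.FEATURE_NAMES)))
    return included, X, exclusions


def fit_cad_score_model(X: np.ndarray, cohort: pd.DataFrame,
                        min_cases: int = 20) -> tuple[sc.CADScoreModel, np.ndarray]:
    """Fit LDA + logistic fusion + scaling on a featurised cohort;
    returns the model and the per-patient integer CAD-scores."""
    y = (cohort["disease_level"] == "significant_cad").to_numpy(int)
    lda = feat.fit_lda(X, y)
    acc = feat.acoustic_scores(X, lda)
    cov = np.column_stack([
        cohort["age"].to_numpy(float),
        (cohort["sex"] == "male").to_numpy(float),
        cohort["hypertension"].to_numpy(float),
    ])
    fusion = sc.fit_logistic(acc, cov, y)
    lp = fusion.linear_predictor(acc, cov[:, 0], cov[:, 1], cov[:, 2])
    anchors = sc.calibrate_scale(lp, y, min_cases=min_cases)
    model = sc.CADScoreModel(lda=lda, fusion=fusion, anchors=anchors)
    scores = sc.scores_from_lp(anchors, lp)
    return model, scores


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the whole study simulation; returns (and optionally
    writes) the report bundle."""
    t_start = time.time()
    bundle: dict = {"config": config.to_dict()}

    def stage(name):
        log.info("stage %-14s t=%.1fs", name, time.time() - t_start)

    try:
        stage("simulate")
        cohort = generate_cohort(config.cohort)
    except Exception as e:  # pragma: no cover - config errors surfaced early
        raise StageError("simulate", e)

    try:
        stage("featurise")
        included, X, exclusions = extract_cohort_features(cohort, config.cohort, config.qc)
        bundle["exclusions"] = exclusions
        bundle["n_total"] = len(cohort)
        bundle["n_included"] = len(included)
    except Exception as e:
        raise StageError("featurise", e)

    try:
        stage("fit")
        model, scores = fit_cad_score_model(X, included, min_cases=config.calibration_min_cases)
        included = included.copy()
        included["cad_score"] = scores
        bundle["model"] = model
    except Exception as e:
        raise StageError("fit", e)

    try:
        stage("ptp")
        included["ptp"] = [
            compute_ptp(config.ptp, a, s, sym)
            for a, s, sym in zip(included["age"], included["sex"], included["symptom"])
        ]
        included["ptp_band"] = [ptp_band(p).value for p in included["ptp"]]
        bundle["cohort"] = included
    except Exception as e:
        raise StageError("ptp", e)

    try:
        stage("reclassify")
        sub = included
        if config.exclude_asymptomatic_from_reclassification:
            sub = included[included["symptom"] != "none"]
        recl = reclassification_table(sub)
        bundle["reclassification"] = recl
        bundle["nri"] = net_reclassification_index(recl)
        bundle["n_symptomatic"] = len(sub)
    except Exception as e:
        raise StageError("reclassify", e)

    try:
        stage("evaluate")
        truth = (included["disease_level"] == "significant_cad").to_numpy()
        pred = included["cad_score"].to_numpy(int) > model.threshold
        cm = confusion_matrix(pred, truth)
        bundle["diagnostics"] = diagnostic_summary(cm)
        bundle["roc"] = roc_auc(included["cad_score"].to_numpy(float), truth)
        bundle["roc_ptp"] = roc_auc(included["ptp"].to_numpy(float), truth)
        bundle["delong_vs_ptp"] = delong_paired_test(
            included["cad_score"].to_numpy(float), included["ptp"].to_numpy(float), truth)
        nlr = bundle["diagnostics"].nlr
        bundle["post_test_negative"] = post_test_probability(cm.positives / cm.total, nlr)
    except Exception as e:
        raise StageError("evaluate", e)

    if config.run_cv:
        try:
            stage("crossval")
            cov = np.column_stack([
                included["age"].to_numpy(float),
                (included["sex"] == "male").to_numpy(float),
                included["hypertension"].to_numpy(float),
            ])
            y = truth.astype(int)
            bundle["cv"] = repeated_cv(X, cov, y, folds=config.cv_folds,
                                       repeats=config.cv_repeats, seed=config.cohort.seed)
        except Exception as e:
            raise StageError("crossval", e)

    stage("done")
    if config.output_dir:
        write_bundle(bundle, config.output_dir)
    return bundle


def evaluate_from_counts(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Full metric block straight from 2x2 counts — the path that
    reproduces any published table of count-derived diagnostics."""
    from .stats import ConfusionMatrix
    cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
    summ = diagnostic_summary(cm)
    prev = cm.positives / cm.total
    report = summ.as_dict()
    report["post_test_probability_negative_pct"] = round(
        100 * post_test_probability(prev, summ.nlr), 1)
    report["post_test_probability_positive_pct"] = round(
        100 * post_test_probability(prev, summ.plr), 1)
    return report


# ---------------------------------------------------------------------------
# report output

def _report_markdown(bundle: dict) -> str:
    d = bundle["diagnostics"].as_dict()
    roc = bundle["roc"]
    lines = [
        "# Simulated study report",
        "",
        f"Patients simulated: {bundle['n_total']}; included after QC: {bundle['n_included']}",
        f"Exclusions: {bundle['exclusions']}",
        "",
        "## Diagnostic performance (significant-CAD vs other)",
        "",
        "| metric | value |",
        "| --- | --- |",
        f"| N: Other | {d['counts']['tn'] + d['counts']['fp']} |",
        f"| N: Significant-CAD | {d['counts']['tp'] + d['counts']['fn']} |",
        f"| Prevalence of CAD | {d['prevalence_pct']}% |",
        f"| True negative | {d['counts']['tn']} |",
        f"| False negative | {d['counts']['fn']} |",
        f"| False positive | {d['counts']['fp']} |",
        f"| True positive | {d['counts']['tp']} |",
        f"| AUC | {roc.auc:.3f} ({roc.ci_low:.3f}-{roc.ci_high:.3f}) |",
        f"| Negative predictive value | {bundle['diagnostics'].npv} |",
        f"| Positive predictive value | {bundle['diagnostics'].ppv} |",
        f"| Sensitivity | {bundle['diagnostics'].sensitivity} |",
        f"| Specificity | {bundle['diagnostics'].specificity} |",
        f"| Likelihood ratio positive | {d['plr']} |",
        f"| Likelihood ratio negative | {d['nlr']} |",
        "",
        f"Post-test probability of significant-CAD after a negative score: "
        f"{100 * bundle['post_test_negative']:.1f}%",
        "",
        "## Reclassification (symptomatic patients)",
        "",
        "```",
        bundle["reclassification"].to_text(),
        "```",
    ]
    if "cv" in bundle:
        cv = bundle["cv"]
        lines += ["", "## Cross-validation",
                  f"Resubstitution AUC {cv.resubstitution_auc:.3f}; "
                  f"mean CV AUC {cv.mean_cv_auc:.3f} "
                  f"({cv.repeats}x{cv.folds}-fold); optimism {cv.optimism:.3f}"]
    return "\n".join(lines) + "\n"


def write_bundle(bundle: dict, output_dir: str | Path) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort_csv(bundle["cohort"], out / "cohort.csv")
    bundle["model"].to_json(out / "model.json")
    (out / "reclassification.json").write_text(
        json.dumps(bundle["reclassification"].as_dict(), indent=1))
    (out / "reclassification.txt").write_text(bundle["reclassification"].to_text() + "\n")
    report = {
        "n_total": bundle["n_total"], "n_included": bundle["n_included"],
        "exclusions": bundle["exclusions"],
        "diagnostics": bundle["diagnostics"].as_dict(),
        "auc": {"value": bundle["roc"].auc,
                "ci": [bundle["roc"].ci_low, bundle["roc"].ci_high]},
        "auc_ptp": bundle["roc_ptp"].auc,
        "delong_vs_ptp_p": bundle["delong_vs_ptp"].p_value,
        "post_test_negative_pct": round(100 * bundle["post_test_negative"], 1),
        "nri": round(bundle["nri"], 3),
    }
    if "cv" in bundle:
        report["cv"] = bundle["cv"].as_dict()
        bundle["cv"].fold_table().to_csv(out / "cv_folds.csv", index=False)
    (out / "report.json").write_text(json.dumps(report, indent=1))
    (out / "report.md").write_text(_report_markdown(bundle))
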