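"""Logistic fusion of the acoustic score with clinical covariates, and
the 0–99 CAD-score scaling.

The acoustic discriminant score is combined with age (years), sex
(male = 1) and hypertension status (systolic BP >= 140 mmHg or on
antihypertensive treatment) by maximum-likelihood logistic regression
against the significant-CAD label.  The resulting linear predictor is
mapped affinely onto a 0–99 integer scale, anchored so that the
empirical 10th percentile of linear predictors among significant-CAD
training patients lands exactly at 20 — i.e. 90 % of diseased training
patients score above the rule-out threshold.  Scores > 20 are
classified abnormal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .features import LDAWeights

PREDICTOR_NAMES = ("acoustic", "age", "male", "hypertension")
THRESHOLD = 20


@dataclass
class LogisticFusion:
    """Fitted fusion coefficients: intercept + one per predictor.

    ``dropped`` lists predictors excluded as non-identifiable (zero
    variance); ``penalized`` marks a ridge fallback after perfect
    separation.
    """

    intercept: float
    coef: dict[str, float]
    penalized: bool = False
    dropped: tuple[str, ...] = ()

    def linear_predictor(self, acoustic, age, male, hypertension) -> np.ndarray:
        vals = {"acoustic": np.asarray(acoustic, dtype=float),
                "age": np.asarray(age, dtype=float),
                "male": np.asarray(male, dtype=float),
                "hypertension": np.asarray(hypertension, dtype=float)}
        lp = np.full_like(vals["age"], self.intercept, dtype=float)
        for name, c in self.coef.items():
            lp = lp + c * vals[name]
        return lp


def fit_logistic(acoustic_scores, covariates, labels,
                 tol: float = 1e-8, ridge_penalty: float = 1e-4) -> LogisticFusion:
    """ML logistic regression of the significant-CAD indicator on
    (acoustic score, age, male, hypertension).

    ``covariates`` is an (n, 3) array-like ordered (age, male,
    hypertension) or a mapping/DataFrame with those columns.  Constant
    predictors are dropped with a warning; perfect separation falls
    back to a ridge-penalised fit flagged via ``penalized``.
    """
    a = np.asarray(acoustic_scores, dtype=float)
    y = np.asarray(labels).astype(float)
    if hasattr(covariates, "keys") or hasattr(covariates, "columns"):
        cov = np.column_stack([np.asarray(covariates[k], dtype=float)
                               for k in ("age", "male", "hypertension")])
    else:
        cov = np.asarray(covariates, dtype=float)
    X = np.column_stack([a, cov])
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")

    keep, dropped = [], []
    for j, name in enumerate(PREDICTOR_NAMES):
        if np.ptp(X[:, j]) == 0:
            dropped.append(name)
            warnings.warn(f"predictor {name!r} is constant; dropped from the fusion model")
        else:
            keep.append(j)
    Xk = sm.add_constant(X[:, keep], has_constant="add")
    names = [PREDICTOR_NAMES[j] for j in keep]

    penalized = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xk).fit(disp=0, tol=tol, maxiter=200)
        params = np.asarray(res.params)
        converged = res.mle_retvals.get("converged", True)
        if not converged or not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 1e4:
            raise PerfectSeparationError("unstable ML fit")
    except (PerfectSeparationError, np.linalg.LinAlgError):
        from sklearn.linear_model import LogisticRegression
        lr = LogisticRegression(penalty="l2", C=1.0 / ridge_penalty,
                                solver="lbfgs", max_iter=2000)
        lr.fit(Xk[:, 1:], y)
        params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        penalized = True
        warnings.warn("perfect separation: ridge-penalized fusion fit used")

    coef = {name: float(c) for name, c in zip(names, params[1:])}
    return LogisticFusion(intercept=float(params[0]), coef=coef,
                          penalized=penalized, dropped=tuple(dropped))


# ---------------------------------------------------------------------------
# scaling to 0-99

@dataclass
class ScalingAnchors:
    """Affine map score = slope * lp + offset, then round and clamp.

    ``slope`` spreads the central 95 % of training linear predictors
    over [5, 75]; ``offset`` pins the 10th percentile of the
    significant-CAD linear predictors to exactly 20.
    """

    slope: float
    offset: float

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("scaling slope must be positive (order-preserving)")

    def map(self, lp) -> np.ndarray:
        return self.slope * np.asarray(lp, dtype=float) + self.offset


def calibrate_scale(linear_predictors, labels,
                    span_quantiles: tuple[float, float] = (0.025, 0.975),
                    span_scores: tuple[float, float] = (5.0, 75.0),
                    anchor_quantile: float = 0.10,
                    anchor_score: float = float(THRESHOLD),
                    min_cases: int = 20) -> ScalingAnchors:
    """Quantile-anchored scaling of the logistic linear predictor.

    The slope maps the ``span_quantiles`` span of *all* training linear
    predictors onto ``span_scores``; the offset then places the
    ``anchor_quantile`` (default 10th percentile, linear-interpolation
    quantile) of the significant-CAD linear predictors at exactly the
    rule-out threshold, so 90 % of diseased training patients map above
    it before rounding.
    """
    lp = np.asarray(linear_predictors, dtype=float)
    y = np.asarray(labels).astype(bool)
    if int(y.sum()) < min_cases:
        raise ValueError(f"need >= {min_cases} significant-CAD training patients, got {int(y.sum())}")
    qlo, qhi = np.quantile(lp, span_quantiles)
    if qhi - qlo <= 0:
        raise ValueError("degenerate linear-predictor spread")
    slope = (span_scores[1] - span_scores[0]) / (qhi - qlo)
    anchor_lp = float(np.quantile(lp[y], anchor_quantile))
    offset = anchor_score - slope * anchor_lp
    return ScalingAnchors(slope=slope, offset=offset)


# ---------------------------------------------------------------------------
# the assembled model

@dataclass
class CADScoreModel:
    """LDA weights + logistic fusion + scaling anchors + threshold 20."""

    lda: LDAWeights
    fusion: LogisticFusion
    anchors: ScalingAnchors
    threshold: int = THRESHOLD

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "lda": self.lda.as_dict(),
            "fusion": {"intercept": self.fusion.intercept, "coef": self.fusion.coef,
                       "penalized": self.fusion.penalized, "dropped": list(self.fusion.dropped)},
            "anchors": {"slope": self.anchors.slope, "offset": self.anchors.offset},
            "threshold": self.threshold,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CADScoreModel":
        d = json.loads(Path(path).read_text())
        return cls(
            lda=LDAWeights(weights=np.asarray(d["lda"]["weights"]),
                           intercept=d["lda"]["intercept"],
                           feature_names=tuple(d["lda"]["feature_names"])),
            fusion=LogisticFusion(intercept=d["fusion"]["intercept"], coef=d["fusion"]["coef"],
                                  penalized=d["fusion"]["penalized"],
                                  dropped=tuple(d["fusion"]["dropped"])),
            anchors=ScalingAnchors(**d["anchors"]),
            threshold=int(d["threshold"]),
        )


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def scores_from_lp(anchors: ScalingAnchors, lp) -> np.ndarray:
    """Integer 0-99 scores from linear predictors (round half-up, clamp)."""
    return np.clip(_round_half_up(anchors.map(lp)), 0, 99).astype(int)


def compute_cad_score(model: CADScoreModel, acoustic, age, male, hypertension):
    """End scores for one patient or a vector of patients.

    Any missing (NaN) covariate raises — mirroring the exclusion of
    patients with missing clinical information.
    """
    arrs = [np.asarray(v, dtype=float) for v in (acoustic, age, male, hypertension)]
    for name, v in zip(("acoustic",) + ("age", "male", "hypertension"), arrs):
        if np.any(~np.isfinite(v)):
            raise ValueError(f"missing value for covariate {name!r}")
    lp = model.fusion.linear_predictor(*arrs)
    out = scores_from_lp(model.anchors, lp)
    return int(out) if np.isscalar(acoustic) or np.ndim(acoustic) == 0 else out


def classify_score(score) -> str:
    """'abnormal' iff score > 20, 'normal' iff score <= 20."""
    s = int(score)
    if not 0 <= s <= 99:
        raise ValueError(f"score out of range [0, 99]: {score}")
    return "abnormal" if s > THRESHOLD else "normal"
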