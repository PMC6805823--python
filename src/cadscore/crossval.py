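"""Repeated stratified cross-validation of the LDA + logistic stages.

Both model stages are refit inside every training fold; out-of-fold
linear predictors are pooled per repeat before computing the AUC (the
alternative — averaging per-fold AUCs — is available via
``pool_scores=False``).  Comparing the mean cross-validated AUC with
the resubstitution AUC quantifies how much the score overfits its
training data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .features import acoustic_scores, fit_lda
from .score import fit_logistic
from .stats import roc_auc


@dataclass
class CVResult:
    fold_aucs: np.ndarray          # (repeats, folds), NaN where a fold had one class
    repeat_aucs: np.ndarray        # pooled out-of-fold AUC per repeat
    resubstitution_auc: float
    oof_scores: np.ndarray         # (repeats, n) out-of-fold linear predictors
    folds: int
    repeats: int

    @property
    def mean_cv_auc(self) -> float:
        return float(np.mean(self.repeat_aucs))

    @property
    def optimism(self) -> float:
        """Resubstitution minus mean cross-validated AUC."""
        return self.resubstitution_auc - self.mean_cv_auc

    def as_dict(self) -> dict:
        return {"mean_cv_auc": self.mean_cv_auc,
                "resubstitution_auc": self.resubstitution_auc,
                "optimism": self.optimism,
                "repeat_aucs": self.repeat_aucs.tolist(),
                "folds": self.folds, "repeats": self.repeats}

    def fold_table(self) -> pd.DataFrame:
        rows = [(r, f, self.fold_aucs[r, f])
                for r in range(self.repeats) for f in range(self.folds)]
        return pd.DataFrame(rows, columns=["repeat", "fold", "auc"])


def _fit_and_predict(features, covariates, labels, train, test) -> np.ndarray:
    lda = fit_lda(features[train], labels[train])
    acc_train = acoustic_scores(features[train], lda)
    acc_test = acoustic_scores(features[test], lda)
    fusion = fit_logistic(acc_train, covariates[train], labels[train])
    return fusion.linear_predictor(acc_test, covariates[test, 0],
                                   covariates[test, 1], covariates[test, 2])


def repeated_cv(features, covariates, labels, folds: int = 10, repeats: int = 50,
                seed: int = 0, pool_scores: bool = True,
                max_redraws: int = 20) -> CVResult:
    """Repeated stratified k-fold CV retraining LDA and logistic stages.

    ``covariates`` is (n, 3): age, male, hypertension.  Repeat r uses
    seed + r, so results are deterministic under a fixed seed.  A fold
    split leaving a training fold without events is redrawn (with a
    warning); ``folds == n`` requests leave-one-out (unstratified).
    """
    X = np.asarray(features, dtype=float)
    C = np.asarray(covariates, dtype=float)
    y = np.asarray(labels).astype(int)
    n = len(y)
    if y.sum() == 0 or y.sum() == n:
        raise ValueError("both classes required")

    fold_aucs = np.full((repeats, folds), np.nan)
    repeat_aucs = np.zeros(repeats)
    oof = np.zeros((repeats, n))
    for r in range(repeats):
        for attempt in range(max_redraws):
            rs = seed + r + attempt * 10007
            if folds == n:
                splitter = KFold(n_splits=folds, shuffle=True, random_state=rs)
                splits = list(splitter.split(X))
            else:
                splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
                splits = list(splitter.split(X, y))
            if all(0 < y[tr].sum() < len(tr) for tr, _ in splits):
                break
            warnings.warn(f"repeat {r}: a training fold lacked events; redrawing folds")
        else:
            raise RuntimeError("could not draw folds with events in every training fold")

        for f, (train, test) in enumerate(splits):
            lp = _fit_and_predict(X, C, y, train, test)
            oof[r, test] = lp
            yt = y[test]
            if 0 < yt.sum() < len(yt):
                fold_aucs[r, f] = roc_auc(lp, yt).auc
        if pool_scores:
            repeat_aucs[r] = roc_auc(oof[r], y).auc
        else:
            repeat_aucs[r] = np.nanmean(fold_aucs[r])

    # resubstitution: fit once on everything, score everything
    full = np.arange(n)
    resub_lp = _fit_and_predict(X, C, y, full, full)
    resub = roc_auc(resub_lp, y).auc
    return CVResult(fold_aucs=fold_aucs, repeat_aucs=repeat_aucs,
                    resubstitution_auc=resub, oof_scores=oof,
                    folds=folds, repeats=repeats)
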