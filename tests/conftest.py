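import numpy as np
import pytest
from hypothesis import settings

from cadscore import CohortConfig, generate_cohort
from cadscore import features as feat
from cadscore import score as sc
from cadscore.pipeline import extract_cohort_features

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


class Study:
    """Fully processed synthetic training study (shared, read-only)."""

    def __init__(self, cohort, X, y, cov, lda, acoustic, fusion, lp, anchors, scores):
        self.cohort = cohort
        self.X = X
        self.y = y
        self.cov = cov
        self.lda = lda
        self.acoustic = acoustic
        self.fusion = fusion
        self.lp = lp
        self.anchors = anchors
        self.scores = scores


@pytest.fixture(scope="session")
def study2000():
    """Default synthetic training cohort (n = 2000, seed 7) carried through
    recording simulation, QC, segmentation, features, LDA, logistic fusion
    and scaling calibration.  Expensive; shared across tests that need the
    full study conditions."""
    cfg = CohortConfig(n=2000, seed=7)
    cohort = generate_cohort(cfg)
    included, X, _ = extract_cohort_features(cohort, cfg)
    y = (included["disease_level"] == "significant_cad").to_numpy(int)
    cov = np.column_stack([
        included["age"].to_numpy(float),
        (included["sex"] == "male").to_numpy(float),
        included["hypertension"].to_numpy(float),
    ])
    lda = feat.fit_lda(X, y)
    acoustic = feat.acoustic_scores(X, lda)
    fusion = sc.fit_logistic(acoustic, cov, y)
    lp = fusion.linear_predictor(acoustic, cov[:, 0], cov[:, 1], cov[:, 2])
    anchors = sc.calibrate_scale(lp, y)
    scores = sc.scores_from_lp(anchors, lp)
    return Study(included, X, y, cov, lda, acoustic, fusion, lp, anchors, scores)


@pytest.fixture(scope="session")
def big_cohort():
    """Covariate-only cohort at n = 10000 for marginal-distribution checks."""
    return generate_cohort(CohortConfig(n=10000, seed=1))
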