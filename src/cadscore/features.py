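"""Acoustic feature extraction and the linear-discriminant acoustic score.

Eight features summarise each recording, computed per beat inside the
segmented systolic/diastolic intervals and aggregated by the median
across beats (the last feature is itself a beat-to-beat variability
measure).  All eight are amplitude-scale invariant — ratios, entropies
or frequencies — so microphone gain does not matter.

The default bank (configurable order is fixed; names are stable across
the package):

1.  dia_band_ratio    log10 diastolic 200–450 Hz band power / total power
2.  sys_band_ratio    log10 systolic 200–450 Hz band power / total power
3.  dia_spectral_entropy   normalised Shannon entropy of the diastolic spectrum
4.  dia_ar_pole_freq  dominant AR(4) pole frequency of diastole (Hz)
5.  dia_sys_rms_ratio log diastolic/systolic RMS
6.  s1_s2_amp_ratio   log S1/S2 envelope peak ratio
7.  dia_hf_fraction   diastolic >250 Hz energy fraction
8.  dia_power_cv      beat-to-beat CV of diastolic murmur-band power

The acoustic score is a two-class Fisher linear discriminant on these
features with shrinkage of the pooled covariance toward its diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .processing import SegmentationResult, envelope
from .synthetic import PCGRecording

FEATURE_NAMES = (
    "dia_band_ratio",
    "sys_band_ratio",
    "dia_spectral_entropy",
    "dia_ar_pole_freq",
    "dia_sys_rms_ratio",
    "s1_s2_amp_ratio",
    "dia_hf_fraction",
    "dia_power_cv",
)

MURMUR_BAND = (200.0, 450.0)
HF_EDGE = 250.0
EPS = 1e-20


def _band_sos(fs: int, lo: float, hi: float):
    return signal.butter(4, [lo / (fs / 2), min(hi / (fs / 2), 0.98)],
                         btype="bandpass", output="sos")


def _interval_power(cum: np.ndarray, fs: int, a: float, b: float) -> float:
    """Mean power in [a, b) seconds from a cumulative sum of squares."""
    i, j = int(a * fs), int(b * fs)
    j = min(j, len(cum) - 1)
    if j <= i:
        return 0.0
    return float(cum[j] - cum[i]) / (j - i)


def _spectral_entropy(x: np.ndarray) -> float:
    if len(x) < 16:
        return np.nan
    psd = np.abs(np.fft.rfft(x - x.mean())) ** 2
    psd = psd[1:]  # drop DC
    tot = psd.sum()
    if tot <= 0:
        return np.nan
    p = psd / tot
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(len(psd)))


def _ar_pole_freq(x: np.ndarray, fs: int, order: int = 4) -> float:
    """Frequency (Hz) of the strongest complex pole of a Yule-Walker
    AR(order) fit; crude spectral-peak tracker."""
    n = len(x)
    if n < 4 * order:
        return np.nan
    x = x - x.mean()
    r = np.correlate(x, x, mode="full")[n - 1: n + order] / n
    if r[0] <= 0:
        return np.nan
    import scipy.linalg as sla
    try:
        a = sla.solve_toeplitz((r[:-1], r[:-1]), r[1:])
    except np.linalg.LinAlgError:
        return np.nan
    roots = np.roots(np.concatenate([[1.0], -a]))
    roots = roots[np.abs(roots.imag) > 1e-9]
    if len(roots) == 0:
        return np.nan
    dom = roots[np.argmax(np.abs(roots))]
    return float(abs(np.angle(dom)) * fs / (2 * np.pi))


def extract_features(recording: PCGRecording, segmentation: SegmentationResult) -> dict[str, float]:
    """Eight-feature summary of one segmented recording.

    Deterministic; uses only samples inside the designated intervals.
    Raises ``ValueError`` on degenerate (zero-length) intervals.
    """
    if len(segmentation.beats) < 5:
        raise ValueError("need at least 5 segmented beats")
    fs = recording.sampling_rate
    x = recording.samples

    band = signal.sosfiltfilt(_band_sos(fs, *MURMUR_BAND), x)
    hf = signal.sosfiltfilt(
        signal.butter(4, HF_EDGE / (fs / 2), btype="highpass", output="sos"), x)
    cum_tot = np.concatenate([[0.0], np.cumsum(x ** 2)])
    cum_band = np.concatenate([[0.0], np.cumsum(band ** 2)])
    cum_hf = np.concatenate([[0.0], np.cumsum(hf ** 2)])
    env = envelope(recording)

    per_beat: dict[str, list[float]] = {k: [] for k in FEATURE_NAMES[:7]}
    dia_band_powers: list[float] = []
    for b in segmentation.beats:
        d0, d1 = b.diastole
        s0, s1 = b.systole
        if d1 - d0 <= 0 or s1 - s0 <= 0 or b.s1_offset <= b.s1_onset or b.s2_offset <= b.s2_onset:
            raise ValueError("degenerate interval in segmentation")
        p_dia_tot = _interval_power(cum_tot, fs, d0, d1)
        p_sys_tot = _interval_power(cum_tot, fs, s0, s1)
        p_dia_band = _interval_power(cum_band, fs, d0, d1)
        p_sys_band = _interval_power(cum_band, fs, s0, s1)
        p_dia_hf = _interval_power(cum_hf, fs, d0, d1)
        dia = x[int(d0 * fs): int(d1 * fs)]

        per_beat["dia_band_ratio"].append(np.log10((p_dia_band + EPS) / (p_dia_tot + EPS)))
        per_beat["sys_band_ratio"].append(np.log10((p_sys_band + EPS) / (p_sys_tot + EPS)))
        per_beat["dia_spectral_entropy"].append(_spectral_entropy(dia))
        per_beat["dia_ar_pole_freq"].append(_ar_pole_freq(dia, fs))
        per_beat["dia_sys_rms_ratio"].append(
            0.5 * np.log10((p_dia_tot + EPS) / (p_sys_tot + EPS)))
        e1 = env[int(b.s1_onset * fs): int(b.s1_offset * fs)]
        e2 = env[int(b.s2_onset * fs): int(b.s2_offset * fs)]
        per_beat["s1_s2_amp_ratio"].append(
            np.log10((e1.max() + EPS) / (e2.max() + EPS)))
        per_beat["dia_hf_fraction"].append((p_dia_hf + EPS) / (p_dia_tot + EPS))
        dia_band_powers.append(p_dia_band)

    out = {k: float(np.nanmedian(v)) for k, v in per_beat.items()}
    dp = np.asarray(dia_band_powers)
    out["dia_power_cv"] = float(np.std(dp, ddof=1) / (np.mean(dp) + EPS))
    if not all(np.isfinite(v) for v in out.values()):
        bad = [k for k, v in out.items() if not np.isfinite(v)]
        raise ValueError(f"non-finite features: {bad}")
    return out


def feature_matrix(feature_dicts: list[dict[str, float]]) -> np.ndarray:
    return np.array([[d[k] for k in FEATURE_NAMES] for d in feature_dicts])


# ---------------------------------------------------------------------------
# linear discriminant

@dataclass
class LDAWeights:
    """Fisher discriminant direction + intercept (midpoint-centred)."""

    weights: np.ndarray
    intercept: float
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)

    def as_dict(self) -> dict:
        return {"weights": self.weights.tolist(), "intercept": self.intercept,
                "feature_names": list(self.feature_names)}


def fit_lda(features: np.ndarray, labels: np.ndarray, shrinkage: float = 0.1,
            feature_names: tuple[str, ...] = FEATURE_NAMES) -> LDAWeights:
    """Two-class Fisher LDA with shrinkage toward the diagonal.

    ``labels`` is the significant-CAD indicator (0/1); the returned
    direction is oriented so higher scores mean more disease-like.
    The pooled within-class covariance S is replaced by
    ``(1-g) S + g diag(S)``, which keeps the solve well-posed even for
    duplicated features.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if X.ndim != 2:
        raise ValueError("features must be 2-D")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    X0, X1 = X[y == 0], X[y == 1]
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError("need >= 2 samples per class")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = len(X0), len(X1)
    S = ((n0 - 1) * np.cov(X0, rowvar=False, ddof=1)
         + (n1 - 1) * np.cov(X1, rowvar=False, ddof=1)) / (n0 + n1 - 2)
    S = np.atleast_2d(S)
    d = np.diag(np.diag(S))
    # guard fully-degenerate diagonals too
    d = d + 1e-12 * np.trace(S) / S.shape[0] * np.eye(S.shape[0])
    Ssh = (1.0 - shrinkage) * S + shrinkage * d
    w = np.linalg.solve(Ssh, mu1 - mu0)
    intercept = -float(w @ (mu0 + mu1) / 2.0)
    return LDAWeights(weights=w, intercept=intercept, feature_names=feature_names)


def acoustic_score(features: np.ndarray | dict[str, float], weights: LDAWeights) -> float:
    """Affine projection of a feature vector onto the discriminant."""
    if isinstance(features, dict):
        features = np.array([features[k] for k in weights.feature_names])
    x = np.asarray(features, dtype=float)
    if x.shape[-1] != len(weights.weights):
        raise ValueError(
            f"dimension mismatch: {x.shape[-1]} features vs {len(weights.weights)} weights")
    return float(x @ weights.weights + weights.intercept)


def acoustic_scores(features: np.ndarray, weights: LDAWeights) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.shape[1] != len(weights.weights):
        raise ValueError("dimension mismatch")
    return X @ weights.weights + weights.intercept
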