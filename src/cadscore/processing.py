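"""Quality control, filtering and segmentation of heart-sound recordings.

The segmenter is envelope-based: the recording is band-passed to the
S1/S2 band (25–150 Hz), the Hilbert envelope is smoothed, candidate
transients are picked, the heart period is estimated from the envelope
autocorrelation, and peaks are decoded into alternating S1/S2 states
under duration constraints derived from the estimated heart rate
(systole shorter than half the period, diastole the remainder).
Interval boundaries partition each beat contiguously, so per-beat
S1 + systole + S2 + diastole durations sum exactly to the RR interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .synthetic import PCGRecording, S1_DURATION, S2_DURATION, systolic_span


class SegmentationError(RuntimeError):
    """Raised when too few heart beats can be identified."""


@dataclass
class QCThresholds:
    min_duration: float = 15.0       # seconds
    min_beats: int = 20
    rr_cov_max: float = 0.2
    s1_ratio_min: float = 2.0        # S1 peak-to-background envelope ratio


@dataclass
class QCVerdict:
    passed: bool
    reason: str  # ok | arrhythmia | noisy_or_weak | too_short

    def __post_init__(self) -> None:
        assert self.passed == (self.reason == "ok")


@dataclass
class Beat:
    s1_onset: float
    s1_offset: float
    s2_onset: float
    s2_offset: float
    next_s1_onset: float

    @property
    def systole(self) -> tuple[float, float]:
        return (self.s1_offset, self.s2_onset)

    @property
    def diastole(self) -> tuple[float, float]:
        return (self.s2_offset, self.next_s1_onset)

    @property
    def rr(self) -> float:
        return self.next_s1_onset - self.s1_onset


@dataclass
class SegmentationResult:
    beats: list[Beat]

    @property
    def rr_series(self) -> np.ndarray:
        return np.array([b.rr for b in self.beats])

    @property
    def s1_onsets(self) -> np.ndarray:
        return np.array([b.s1_onset for b in self.beats])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps([b.__dict__ for b in self.beats], indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SegmentationResult":
        return cls([Beat(**d) for d in json.loads(Path(path).read_text())])


# ---------------------------------------------------------------------------

def bandpass_filter(recording: PCGRecording, low_hz: float, high_hz: float) -> PCGRecording:
    """Zero-phase Butterworth band-pass; length-preserving so existing
    annotations stay aligned."""
    fs = recording.sampling_rate
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError(f"invalid band ({low_hz}, {high_hz}) for fs={fs}")
    sos = signal.butter(4, [low_hz / (fs / 2), high_hz / (fs / 2)], btype="bandpass", output="sos")
    y = signal.sosfiltfilt(sos, recording.samples)
    return PCGRecording(samples=y, sampling_rate=fs,
                        annotations=recording.annotations, pretest=recording.pretest)


def envelope(recording: PCGRecording, band: tuple[float, float] = (25.0, 150.0),
             smooth_ms: float = 25.0) -> np.ndarray:
    """Smoothed Hilbert envelope of the band-passed signal (centred
    moving average, so no group delay)."""
    filt = bandpass_filter(recording, *band)
    env = np.abs(signal.hilbert(filt.samples))
    win = max(int(smooth_ms / 1000 * recording.sampling_rate), 1)
    kernel = np.ones(win) / win
    return np.convolve(env, kernel, mode="same")


def _estimate_period(env: np.ndarray, fs: int,
                     lag_range: tuple[float, float] = (0.4, 1.6)) -> float | None:
    e = env - env.mean()
    nmax = int(lag_range[1] * fs)
    if len(e) < 2 * nmax:
        nmax = len(e) // 2
    ac = signal.fftconvolve(e, e[::-1], mode="full")[len(e) - 1:]
    ac = ac[: nmax + 1]
    lo = int(lag_range[0] * fs)
    if nmax <= lo + 2 or ac[0] <= 0:
        return None
    seg = ac[lo:]
    k = int(np.argmax(seg))
    if seg[k] < 0.1 * ac[0]:
        return None
    return (lo + k) / fs


def _pick_peaks(env: np.ndarray, fs: int) -> tuple[np.ndarray, np.ndarray, float]:
    floor = float(np.median(env))
    height = floor + 0.35 * (np.percentile(env, 99.5) - floor)
    idx, props = signal.find_peaks(env, height=height, distance=int(0.15 * fs))
    return idx, env[idx], floor


def _detect_s1_s2(env: np.ndarray, fs: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Return (s1 peak indices, s2 peak indices aligned per beat, period).

    Duration-constrained decoding: the heart period T from the envelope
    autocorrelation defines a comb; starting at the strongest peak, the
    next S1 is the best peak in [0.55 T, 1.7 T] after the current one,
    scored by envelope height minus a penalty on deviation from T
    (S2 candidates lose on both counts).  S2 is then the tallest peak
    strictly inside each S1–S1 interval.
    """
    period = _estimate_period(env, fs)
    idx, heights, floor = _pick_peaks(env, fs)
    if len(idx) < 4:
        raise SegmentationError("too few transients detected")
    if period is None:
        # irregular rhythm defeats the autocorrelation; peaks alternate
        # S1/S2 so two consecutive gaps approximate one beat
        t = idx / fs
        period = float(np.median(t[2:] - t[:-2])) if len(t) > 2 else float(np.median(np.diff(t)) * 2)
        if not 0.3 <= period <= 2.5:
            raise SegmentationError("no plausible heart period found")
    labels = _viterbi_labels(idx / fs, heights / max(np.median(heights), 1e-12))

    s1_list, s2_list = [], []
    pending_s1 = None
    for i, lab in enumerate(labels):
        if lab == 0:  # S1
            pending_s1 = idx[i]
        elif lab == 1 and pending_s1 is not None:  # S2 closing a beat
            s1_list.append(pending_s1)
            s2_list.append(idx[i])
            pending_s1 = None
    if len(s1_list) < 2:
        raise SegmentationError("could not decode S1/S2 sequence")
    return np.asarray(s1_list), np.asarray(s2_list), period


# duration windows (seconds) for the peak-label decoder
_SYS_GAP = (0.20, 0.45)      # S1 -> S2 (systolic span, heart-rate bounded)
_DIA_GAP = (0.15, 1.60)      # S2 -> next S1 (diastole)
_SKIP_GAP = (0.40, 1.90)     # one sound missed


def _viterbi_labels(t: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Label envelope peaks as S1 (0), S2 (1) or noise (-1) by decoding
    the alternating-state sequence maximizing total envelope height
    under per-transition duration windows.

    S1 is favoured as the taller of the pair; skipping a sound costs a
    fixed penalty, so spurious low peaks are left unlabelled.
    """
    n = len(t)
    NEG = -1e12
    dp = np.full((n, 2), NEG)
    back = np.full((n, 2, 2), -1, dtype=int)
    for i in range(n):
        dp[i, 0] = h[i]          # fresh start as S1
        dp[i, 1] = 0.8 * h[i]    # fresh start as S2
        j = i - 1
        while j >= 0 and t[i] - t[j] <= 2.0:
            g = t[i] - t[j]
            for s_prev in (0, 1):
                base = dp[j, s_prev]
                if base <= NEG / 2:
                    continue
                # -> S1
                if s_prev == 1 and _DIA_GAP[0] <= g <= _DIA_GAP[1]:
                    sc = base + h[i]
                elif s_prev == 0 and _SKIP_GAP[0] <= g <= _SKIP_GAP[1]:
                    sc = base + h[i] - 0.6            # S2 of previous beat missed
                else:
                    sc = None
                if sc is not None and sc > dp[i, 0]:
                    dp[i, 0] = sc
                    back[i, 0] = (j, s_prev)
                # -> S2
                if s_prev == 0 and _SYS_GAP[0] <= g <= _SYS_GAP[1]:
                    sc = base + 0.8 * h[i] + 0.5 * (h[j] - h[i])  # S1 taller than S2
                elif s_prev == 1 and _SKIP_GAP[0] <= g <= _SKIP_GAP[1]:
                    sc = base + 0.8 * h[i] - 0.8      # S1 of this beat missed
                else:
                    sc = None
                if sc is not None and sc > dp[i, 1]:
                    dp[i, 1] = sc
                    back[i, 1] = (j, s_prev)
            j -= 1

    labels = np.full(n, -1, dtype=int)
    i, s = np.unravel_index(np.argmax(dp), dp.shape)
    while i >= 0:
        labels[i] = s
        i, s = back[i, s]
    return labels


def _robust_rr(s1_idx: np.ndarray, fs: int) -> np.ndarray:
    """RR series with missed/extra-beat artifacts removed: intervals
    outside [0.5, 1.6] x median are detection errors, not physiology."""
    rr = np.diff(np.sort(s1_idx)) / fs
    rr = rr[(rr > 0.3) & (rr < 2.5)]
    if len(rr) == 0:
        return rr
    med = np.median(rr)
    return rr[(rr > 0.5 * med) & (rr < 1.6 * med)]


def _refine_onset(env: np.ndarray, peak: int, fs: int, floor: float,
                  nominal_dur: float) -> int:
    """Walk back from an envelope peak to the 10% crossing (relative to
    the local peak height above floor); clamp to half the nominal
    transient duration if the envelope never drops (noise floor)."""
    thresh = floor + 0.10 * (env[peak] - floor)
    limit = max(0, peak - int(1.2 * nominal_dur * fs))
    i = peak
    while i > limit and env[i] > thresh:
        i -= 1
    if env[i] > thresh:  # never crossed: fall back to nominal half-width
        i = max(0, peak - int(0.5 * nominal_dur * fs))
    return i


def _refine_offset(env: np.ndarray, peak: int, fs: int, floor: float,
                   nominal_dur: float) -> int:
    thresh = floor + 0.10 * (env[peak] - floor)
    limit = min(len(env) - 1, peak + int(1.2 * nominal_dur * fs))
    i = peak
    while i < limit and env[i] > thresh:
        i += 1
    if env[i] > thresh:
        i = min(len(env) - 1, peak + int(0.5 * nominal_dur * fs))
    return i


def segment_heart_sounds(recording: PCGRecording) -> SegmentationResult:
    """Segment a recording into per-beat S1 / systole / S2 / diastole
    intervals. Raises :class:`SegmentationError` below 5 decoded beats."""
    fs = recording.sampling_rate
    env = envelope(recording)
    s1_idx, s2_idx, period = _detect_s1_s2(env, fs)
    floor = float(np.median(env))

    beats: list[Beat] = []
    for k in range(len(s1_idx) - 1):
        s1, s2, s1_next = s1_idx[k], s2_idx[k], s1_idx[k + 1]
        rr = (s1_next - s1) / fs
        if not 0.35 <= rr <= 2.0:
            continue
        on1 = _refine_onset(env, s1, fs, floor, S1_DURATION)
        off1 = _refine_offset(env, s1, fs, floor, S1_DURATION)
        on2 = _refine_onset(env, s2, fs, floor, S2_DURATION)
        off2 = _refine_offset(env, s2, fs, floor, S2_DURATION)
        on1_next = _refine_onset(env, s1_next, fs, floor, S1_DURATION)
        if not on1 < off1 < on2 < off2 < on1_next:
            continue
        beats.append(Beat(
            s1_onset=on1 / fs, s1_offset=off1 / fs,
            s2_onset=on2 / fs, s2_offset=off2 / fs,
            next_s1_onset=on1_next / fs,
        ))
    if len(beats) < 5:
        raise SegmentationError(f"only {len(beats)} beats decoded")
    return SegmentationResult(beats)


# ---------------------------------------------------------------------------

def quality_check(recording: PCGRecording,
                  thresholds: QCThresholds | None = None) -> QCVerdict:
    """Pre-test quality control.  Always returns a verdict: too-short
    recording, weak/absent heart-sound transients, or arrhythmia
    (excessive RR variability); otherwise ok."""
    th = thresholds or QCThresholds()
    if recording.duration < th.min_duration:
        return QCVerdict(False, "too_short")
    fs = recording.sampling_rate
    env = envelope(recording)
    floor = float(np.median(env))
    idx, heights, _ = _pick_peaks(env, fs)
    expected_beats = recording.duration / 1.5  # very permissive lower bound
    if len(idx) < max(th.min_beats, int(expected_beats * 0.4)):
        return QCVerdict(False, "noisy_or_weak")
    if float(np.mean(heights)) < th.s1_ratio_min * max(floor, 1e-12):
        return QCVerdict(False, "noisy_or_weak")
    try:
        s1_idx, _, _ = _detect_s1_s2(env, fs)
    except SegmentationError:
        return QCVerdict(False, "noisy_or_weak")
    rr = _robust_rr(s1_idx, fs)
    # attribute excessive RR variability before the beat-count check:
    # arrhythmic rhythms also defeat the beat decoder
    if len(rr) >= 8:
        cov = float(np.std(rr, ddof=1) / np.mean(rr))
        if cov > th.rr_cov_max:
            return QCVerdict(False, "arrhythmia")
    if len(s1_idx) < th.min_beats or len(rr) < 3:
        return QCVerdict(False, "noisy_or_weak")
    return QCVerdict(True, "ok")
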