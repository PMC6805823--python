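"""Synthetic cohort and phonocardiogram (PCG) generation.

Stands in for the pooled clinical databases the acoustic CAD-score was
developed on: it draws per-patient covariates (age, sex, hypertension,
symptoms, BMI, diabetes) conditional on a three-level disease status
(non-CAD / mild-CAD / significant-CAD), and renders for each patient a
heart-sound recording in which a weak band-limited diastolic murmur —
the acoustic signature attributed to post-stenotic turbulent coronary
flow — grows with disease severity.

The murmur model is a documented stand-in, not a claim about the real
device's signal: decaying S1/S2 transients (20–60 Hz), heart-rate
dependent systolic duration, 200–500 Hz diastolic noise bursts whose
power scales with disease level, and additive broadband noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

DISEASE_LEVELS = ("non_cad", "mild_cad", "significant_cad")
SYMPTOMS = ("typical", "atypical", "non_specific", "none")
SEXES = ("male", "female")

#: canonical column order for cohort CSV round-trips
COHORT_COLUMNS = [
    "patient_id", "age", "sex", "hypertension", "symptom", "bmi",
    "diabetes", "disease_level", "ptp", "cad_score",
]


@dataclass
class PatientRecord:
    """One patient: covariates, disease level and (optional) scores."""

    patient_id: str
    age: float
    sex: str
    hypertension: bool
    symptom: str
    bmi: float
    diabetes: bool
    disease_level: str
    ptp: float | None = None
    cad_score: int | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.symptom not in SYMPTOMS:
            raise ValueError(f"unknown symptom {self.symptom!r}")
        if self.disease_level not in DISEASE_LEVELS:
            raise ValueError(f"unknown disease level {self.disease_level!r}")
        if self.ptp is not None and not 0.0 <= self.ptp <= 1.0:
            raise ValueError(f"ptp out of [0, 1]: {self.ptp}")
        if self.cad_score is not None and not 0 <= self.cad_score <= 99:
            raise ValueError(f"cad_score out of [0, 99]: {self.cad_score}")


@dataclass
class CohortConfig:
    """All knobs of the synthetic study.

    Covariate marginals follow the pooled baseline table of the source
    cohorts (age 58.3 ± 8.4 y, 52.8 % female, 58.5 % hypertension,
    symptom mix ~22/27/29/22 %), and the disease mix is 46.4 % non-CAD,
    44.2 % mild-CAD, 9.4 % significant-CAD.  Per-level offsets give the
    clinical covariates a realistic association with disease (older,
    more male, more hypertensive, more typical chest pain in
    significant-CAD) while keeping the marginals within a percent or
    two of the configured values.
    """

    n: int = 2000
    prevalence: tuple[float, float, float] = (0.464, 0.442, 0.094)
    seed: int = 0

    # covariates (marginal targets + per-disease-level structure)
    age_mean: float = 58.3
    age_sd: float = 8.4
    age_shift_by_level: tuple[float, float, float] = (-0.6, 0.0, 3.0)
    female_frac_by_level: tuple[float, float, float] = (0.562, 0.520, 0.400)
    hypertension_frac_by_level: tuple[float, float, float] = (0.545, 0.605, 0.660)
    # rows: disease level; cols: typical, atypical, non_specific, none
    symptom_mix_by_level: tuple[tuple[float, ...], ...] = (
        (0.19, 0.27, 0.31, 0.23),
        (0.21, 0.28, 0.29, 0.22),
        (0.42, 0.25, 0.20, 0.13),
    )
    bmi_mean: float = 26.9
    bmi_sd: float = 4.2
    diabetes_frac_by_level: tuple[float, float, float] = (0.045, 0.055, 0.100)

    # acoustics
    sampling_rate: int = 1000
    duration: float = 150.0          # main recording, seconds
    pretest_duration: float = 30.0   # quality-control segment, seconds
    heart_rate_mean: float = 65.0
    heart_rate_sd: float = 8.0
    heart_rate_range: tuple[float, float] = (45.0, 110.0)
    murmur_scale: float = 1.0        # global effect-size multiplier (0 = off)
    murmur_amp_by_level: tuple[float, float, float] = (0.013, 0.016, 0.022)
    murmur_sigma: float = 0.9        # lognormal patient-to-patient spread
    murmur_band: tuple[float, float] = (200.0, 450.0)
    noise_level: float = 0.02        # broadband noise RMS (S1 peak ≈ 1)
    arrhythmia_fraction: float = 0.011
    arrhythmia_rr_cov: float = 0.30  # RR coefficient of variation if arrhythmic
    normal_rr_cov: float = 0.03

    def __post_init__(self) -> None:
        p = np.asarray(self.prevalence, dtype=float)
        if p.size != 3 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"prevalence must be 3 non-negative probabilities summing to 1, got {self.prevalence}"
            )
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


@dataclass
class PCGRecording:
    """Mono heart-sound waveform plus ground-truth beat annotations."""

    samples: np.ndarray
    sampling_rate: int
    annotations: dict | None = None
    pretest: "PCGRecording | None" = None

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


# ---------------------------------------------------------------------------
# cohort generation

def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a cohort of ``config.n`` patients; deterministic under the seed.

    Returns a DataFrame with :data:`COHORT_COLUMNS`; ``ptp`` and
    ``cad_score`` start as NaN and are filled in by later stages.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    level_idx = rng.choice(3, size=n, p=np.asarray(config.prevalence) / np.sum(config.prevalence))

    shifts = np.asarray(config.age_shift_by_level)
    age = rng.normal(config.age_mean, config.age_sd, size=n) + shifts[level_idx]
    age = np.clip(age, 20.0, 95.0)

    female_p = np.asarray(config.female_frac_by_level)[level_idx]
    sex = np.where(rng.random(n) < female_p, "female", "male")

    ht = rng.random(n) < np.asarray(config.hypertension_frac_by_level)[level_idx]

    symptom = np.empty(n, dtype=object)
    mix = np.asarray(config.symptom_mix_by_level, dtype=float)
    mix = mix / mix.sum(axis=1, keepdims=True)
    for lev in range(3):
        mask = level_idx == lev
        symptom[mask] = rng.choice(SYMPTOMS, size=int(mask.sum()), p=mix[lev])

    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, size=n), 15.0, 55.0)
    diabetes = rng.random(n) < np.asarray(config.diabetes_frac_by_level)[level_idx]

    df = pd.DataFrame({
        "patient_id": [f"P{i:05d}" for i in range(n)],
        "age": np.round(age, 1),
        "sex": sex,
        "hypertension": ht,
        "symptom": symptom,
        "bmi": np.round(bmi, 1),
        "diabetes": diabetes,
        "disease_level": np.asarray(DISEASE_LEVELS, dtype=object)[level_idx],
        "ptp": np.nan,
        "cad_score": np.nan,
    })
    return df


def cohort_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for row in df.itertuples(index=False):
        records.append(PatientRecord(
            patient_id=row.patient_id, age=float(row.age), sex=row.sex,
            hypertension=bool(row.hypertension), symptom=row.symptom,
            bmi=float(row.bmi), diabetes=bool(row.diabetes),
            disease_level=row.disease_level,
            ptp=None if pd.isna(row.ptp) else float(row.ptp),
            cad_score=None if pd.isna(row.cad_score) else int(row.cad_score),
        ))
    return records


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df[COHORT_COLUMNS]


def cohort_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Baseline-characteristics table: mean ± SD rows for continuous
    variables, count (percent) rows for categorical ones."""
    if len(df) == 0:
        raise ValueError("empty cohort")
    n = len(df)
    rows: list[tuple[str, str]] = [("N", str(n))]

    def cont(label, x):
        rows.append((label, f"{np.mean(x):.1f} ± {np.std(x, ddof=1) if len(x) > 1 else 0.0:.1f}"))

    def cat(label, count):
        rows.append((label, f"{count} ({100.0 * count / n:.1f}%)"))

    cont("Age", df["age"].to_numpy(float))
    cat("Sex (female)", int((df["sex"] == "female").sum()))
    cont("BMI", df["bmi"].to_numpy(float))
    cat("Hypertension", int(df["hypertension"].sum()))
    cat("Diabetes", int(df["diabetes"].sum()))
    for s, label in [("typical", "Typical chest pain"), ("atypical", "Atypical chest pain"),
                     ("non_specific", "Non-specific symptoms"), ("none", "None")]:
        cat(f"Symptoms: {label}", int((df["symptom"] == s).sum()))
    for lev, label in zip(DISEASE_LEVELS, ("Non-CAD", "Mild-CAD", "Significant-CAD")):
        cat(label, int((df["disease_level"] == lev).sum()))
    return pd.DataFrame(rows, columns=["variable", "value"])


# ---------------------------------------------------------------------------
# phonocardiogram synthesis

def _gabor(t: np.ndarray, center: float, freq: float, width: float) -> np.ndarray:
    """Gaussian-windowed cosine transient (decaying oscillation)."""
    return np.exp(-0.5 * ((t - center) / width) ** 2) * np.cos(2 * np.pi * freq * (t - center))


def systolic_span(heart_rate: float) -> float:
    """S1-onset-to-S2-onset span in seconds; shortens with heart rate."""
    return 0.35 - 0.0012 * (heart_rate - 60.0)


S1_DURATION = 0.12
S2_DURATION = 0.10


def _patient_rng(config: CohortConfig, patient_index: int, repeat: int) -> np.random.Generator:
    # independent stream per (cohort seed, patient, repeat)
    return np.random.default_rng([config.seed, 104729, patient_index, repeat])


def _render_pcg(rng: np.random.Generator, config: CohortConfig, duration: float,
                heart_rate: float, rr_cov: float, murmur_rms: float) -> PCGRecording:
    fs = config.sampling_rate
    n_samp = int(round(duration * fs))
    t = np.arange(n_samp) / fs

    rr_mean = 60.0 / heart_rate
    max_beats = int(duration / rr_mean) + 8
    rr = rr_mean * (1.0 + rr_cov * np.clip(rng.standard_normal(max_beats), -2.5, 2.5))
    rr = np.clip(rr, 0.35, 2.0)
    s1_onsets = 0.2 + np.concatenate([[0.0], np.cumsum(rr[:-1])])
    sys_span = systolic_span(heart_rate)
    # keep only beats fully inside the recording
    keep = s1_onsets + sys_span + S2_DURATION + 0.05 < duration
    s1_onsets = s1_onsets[keep]
    s2_onsets = s1_onsets + sys_span

    x = rng.normal(0.0, config.noise_level, n_samp)

    f1 = 35.0 + rng.normal(0, 3)
    f2 = 55.0 + rng.normal(0, 3)
    for u, v in zip(s1_onsets, s2_onsets):
        a1 = 1.0 * (1 + 0.08 * rng.standard_normal())
        a2 = 0.8 * (1 + 0.08 * rng.standard_normal())
        c1, w1 = u + S1_DURATION / 2, S1_DURATION / 6
        c2, w2 = v + S2_DURATION / 2, S2_DURATION / 6
        i0, i1 = int(max(0, (u - 0.05) * fs)), int(min(n_samp, (u + S1_DURATION + 0.05) * fs))
        x[i0:i1] += a1 * _gabor(t[i0:i1], c1, f1, w1)
        j0, j1 = int(max(0, (v - 0.05) * fs)), int(min(n_samp, (v + S2_DURATION + 0.05) * fs))
        x[j0:j1] += a2 * _gabor(t[j0:j1], c2, f2, w2)

    if murmur_rms > 0:
        lo, hi = config.murmur_band
        sos = signal.butter(4, [lo / (fs / 2), min(hi / (fs / 2), 0.98)], btype="bandpass", output="sos")
        band = signal.sosfilt(sos, rng.standard_normal(n_samp))
        band /= max(np.std(band), 1e-12)
        gate = np.zeros(n_samp)
        dia_starts = s2_onsets + S2_DURATION
        dia_ends = np.append(s1_onsets[1:], duration)
        for ds, de in zip(dia_starts, dia_ends):
            if de - ds < 0.08:
                continue
            m0, m1 = ds + 0.02, ds + 0.75 * (de - ds)
            k0, k1 = int(m0 * fs), int(min(m1 * fs, n_samp))
            if k1 - k0 < 8:
                continue
            gate[k0:k1] = signal.windows.tukey(k1 - k0, alpha=0.4)
        x += murmur_rms * np.sqrt(3.0) * band * gate  # sqrt(3): gate duty ~1/3

    ann = {
        "s1_onsets": s1_onsets.tolist(),
        "s2_onsets": s2_onsets.tolist(),
        "s1_duration": S1_DURATION,
        "s2_duration": S2_DURATION,
        "heart_rate": float(heart_rate),
        "rr_cov": float(rr_cov),
        "murmur_rms": float(murmur_rms),
    }
    return PCGRecording(samples=x, sampling_rate=fs, annotations=ann)


def simulate_pcg(patient: PatientRecord | pd.Series, config: CohortConfig,
                 patient_index: int | None = None, repeat: int = 0) -> PCGRecording:
    """Simulate the main recording (default 150 s) for one patient, with a
    quality-control pre-test segment (default 30 s) attached as ``.pretest``.

    ``repeat`` selects an independent noise realisation for the same
    patient (used for repeatability analyses); patient physiology
    (heart rate, murmur strength, arrhythmia status) is tied to the
    patient, not the repeat.
    """
    if config.sampling_rate <= 0:
        raise ValueError("sampling rate must be positive")
    if isinstance(patient, PatientRecord):
        level = patient.disease_level
        idx = patient_index if patient_index is not None else int(patient.patient_id.lstrip("P") or 0)
    else:
        level = patient["disease_level"]
        idx = patient_index if patient_index is not None else int(str(patient["patient_id"]).lstrip("P"))
    if level not in DISEASE_LEVELS:
        raise ValueError(f"patient has no valid disease level: {level!r}")
    lev = DISEASE_LEVELS.index(level)

    prng = _patient_rng(config, idx, 0)  # physiology: repeat-invariant
    lo, hi = config.heart_rate_range
    hr = float(np.clip(prng.normal(config.heart_rate_mean, config.heart_rate_sd), lo, hi))
    arrhythmic = prng.random() < config.arrhythmia_fraction
    rr_cov = config.arrhythmia_rr_cov if arrhythmic else config.normal_rr_cov
    base = config.murmur_amp_by_level[lev]
    murmur = config.murmur_scale * base * float(np.exp(config.murmur_sigma * prng.standard_normal()))

    nrng = _patient_rng(config, idx, repeat + 1)  # noise: repeat-specific
    rec = _render_pcg(nrng, config, config.duration, hr, rr_cov, murmur)
    pre = _render_pcg(nrng, config, config.pretest_duration, hr, rr_cov, murmur)
    rec.pretest = pre
    return rec


# ---------------------------------------------------------------------------
# WAV + annotation I/O

def write_wav(recording: PCGRecording, path: str | Path) -> None:
    """16-bit PCM mono WAV; peak-normalised to 0.9 full scale."""
    x = recording.samples
    peak = max(np.max(np.abs(x)), 1e-12)
    wavfile.write(str(path), recording.sampling_rate,
                  np.round(x / peak * 0.9 * 32767).astype(np.int16))
    if recording.annotations is not None:
        Path(str(path) + ".json").write_text(json.dumps(recording.annotations, indent=1))


def read_wav(path: str | Path) -> PCGRecording:
    fs, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError("expected mono WAV")
    x = data.astype(float) / 32767.0
    ann_path = Path(str(path) + ".json")
    ann = json.loads(ann_path.read_text()) if ann_path.exists() else None
    return PCGRecording(samples=x, sampling_rate=int(fs), annotations=ann)
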