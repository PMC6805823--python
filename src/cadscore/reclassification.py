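"""Pre-test probability, risk bands and the down-only reclassification
scheme with its net reclassification index (NRI).

Pre-test probability (PTP) of obstructive CAD comes from a logistic
model in age, sex and symptom typicality (Diamond–Forrester form).
Patients are banded low (< 15 %), intermediate (15–85 %, both edges
inclusive) or high (> 85 %).  The scheme re-assigns intermediate-PTP
patients with a CAD-score <= 20 to the low band; nobody moves up and
low/high patients are untouched.  The binary NRI is then

    NRI = (up_events - down_events)/events
        + (down_nonevents - up_nonevents)/nonevents

where events are significant-CAD patients; with a down-only scheme the
"up" terms are zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .score import THRESHOLD


class RiskClass(str, Enum):
    low = "low"
    intermediate = "intermediate"
    high = "high"

    def __lt__(self, other: "RiskClass") -> bool:
        order = ["low", "intermediate", "high"]
        return order.index(self.value) < order.index(other.value)


class DiseaseLevel(str, Enum):
    non_cad = "non_cad"
    mild_cad = "mild_cad"
    significant_cad = "significant_cad"


LOW_EDGE = 0.15
HIGH_EDGE = 0.85

#: Default PTP coefficients.  SYNTHETIC stand-in: the published updated
#: Diamond-Forrester coefficients are not reproduced here; these values
#: are chosen so that PTP rises with age, is higher in men and with more
#: typical chest pain, and gives a guideline-like band distribution
#: (mostly intermediate) on the default synthetic cohort.  Replace via
#: configuration to use an externally sourced model.
DEFAULT_PTP_COEFFICIENTS = {
    "intercept": -6.1,
    "age": 0.072,
    "male": 1.35,
    "symptom": {"typical": 1.6, "atypical": 0.8, "non_specific": 0.3, "none": 0.0},
}


@dataclass
class PTPModel:
    """Logistic PTP model: logit = intercept + b_age*age + b_male*male +
    symptom coefficient.  Symptom categories are fully configurable so
    non-Diamond-Forrester categories ('non_specific', 'none') can carry
    their own coefficient."""

    intercept: float
    age: float
    male: float
    symptom: dict[str, float]

    @classmethod
    def default(cls) -> "PTPModel":
        c = DEFAULT_PTP_COEFFICIENTS
        return cls(intercept=c["intercept"], age=c["age"], male=c["male"],
                   symptom=dict(c["symptom"]))


def compute_ptp(model: PTPModel, age: float, sex: str, symptom: str) -> float:
    """Inverse-logit pre-test probability, strictly inside (0, 1)."""
    if symptom not in model.symptom:
        raise KeyError(f"no PTP coefficient configured for symptom {symptom!r}")
    lp = (model.intercept + model.age * float(age)
          + model.male * (1.0 if sex == "male" else 0.0)
          + model.symptom[symptom])
    return float(1.0 / (1.0 + np.exp(-lp)))


def ptp_band(ptp: float) -> RiskClass:
    """low < 15 %; intermediate 15-85 % (edges inclusive); high > 85 %."""
    if not 0.0 <= ptp <= 1.0:
        raise ValueError(f"ptp out of [0, 1]: {ptp}")
    if ptp < LOW_EDGE:
        return RiskClass.low
    if ptp > HIGH_EDGE:
        return RiskClass.high
    return RiskClass.intermediate


class UnclassifiableError(ValueError):
    """No imaging modality result available to assign a disease level."""


def assign_disease_level(cacs: float | None = None,
                         cta_stenosis_pct: float | None = None,
                         cag_stenosis_pct: float | None = None) -> DiseaseLevel:
    """Three-level disease coding from imaging results.

    significant-CAD: invasive angiography (CAG) stenosis >= 50 % diameter
    reduction.  non-CAD: calcium score zero and no stenosis on CT
    angiography.  Everything else with any positive finding: mild-CAD.
    ``None`` means the modality was not performed / found nothing.
    """
    if cacs is None and cta_stenosis_pct is None and cag_stenosis_pct is None:
        raise UnclassifiableError("no modality data; disease level unassignable")
    if cag_stenosis_pct is not None and cag_stenosis_pct >= 50.0:
        return DiseaseLevel.significant_cad
    cacs_zero = cacs is None or cacs == 0
    no_cta_sten = cta_stenosis_pct is None or cta_stenosis_pct == 0
    no_cag_sten = cag_stenosis_pct is None or cag_stenosis_pct == 0
    if cacs_zero and no_cta_sten and no_cag_sten:
        return DiseaseLevel.non_cad
    return DiseaseLevel.mild_cad


def reclassify(pre: RiskClass, cad_score: int) -> RiskClass:
    """Down-only scheme: intermediate + score <= 20 -> low; low and high
    pass through unchanged."""
    pre = RiskClass(pre)
    if pre is RiskClass.intermediate and int(cad_score) <= THRESHOLD:
        return RiskClass.low
    return pre


# ---------------------------------------------------------------------------

@dataclass
class ReclassificationResult:
    """Pre/post band counts split by event status, plus movement totals.

    ``events`` are significant-CAD patients.  ``pre``/``post`` map band
    name -> count; ``*_events`` count events inside each band.
    """

    pre: dict[str, int]
    post: dict[str, int]
    pre_events: dict[str, int]
    post_events: dict[str, int]
    down_events: int
    down_nonevents: int
    up_events: int
    up_nonevents: int
    events: int
    nonevents: int

    @property
    def n(self) -> int:
        return self.events + self.nonevents

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["nri"] = net_reclassification_index(self)
        return d

    def to_text(self) -> str:
        lines = [f"{'band':<14}{'pre':>8}{'post':>8}{'pre events':>12}{'post events':>13}"]
        for b in ("low", "intermediate", "high"):
            lines.append(f"{b:<14}{self.pre[b]:>8}{self.post[b]:>8}"
                         f"{self.pre_events[b]:>12}{self.post_events[b]:>13}")
        lines.append(f"moved down: {self.down_events + self.down_nonevents} "
                     f"({self.down_events} events, {self.down_nonevents} non-events); "
                     f"NRI = {net_reclassification_index(self):.3f}")
        return "\n".join(lines)


def reclassification_table(cohort: pd.DataFrame) -> ReclassificationResult:
    """Apply the scheme to a cohort table.

    Requires columns ``ptp``, ``cad_score`` and ``disease_level`` to be
    populated for every row; offending patients are listed otherwise.
    """
    required = ["ptp", "cad_score", "disease_level"]
    bad = cohort.index[cohort[required].isna().any(axis=1)]
    if len(bad):
        ids = cohort.loc[bad, "patient_id"].tolist() if "patient_id" in cohort else list(bad)
        raise ValueError(f"patients missing ptp/cad_score/disease_level: {ids[:10]}"
                         + ("..." if len(ids) > 10 else ""))
    pre_bands = [ptp_band(p).value for p in cohort["ptp"]]
    post_bands = [reclassify(RiskClass(b), int(s)).value
                  for b, s in zip(pre_bands, cohort["cad_score"])]
    event = (cohort["disease_level"] == DiseaseLevel.significant_cad.value).to_numpy()

    bands = ("low", "intermediate", "high")
    pre = {b: pre_bands.count(b) for b in bands}
    post = {b: post_bands.count(b) for b in bands}
    pre_events = {b: int(sum(e for bb, e in zip(pre_bands, event) if bb == b)) for b in bands}
    post_events = {b: int(sum(e for bb, e in zip(post_bands, event) if bb == b)) for b in bands}
    order = {b: i for i, b in enumerate(bands)}
    moved_down = np.array([order[pb] > order[qb] for pb, qb in zip(pre_bands, post_bands)])
    moved_up = np.array([order[pb] < order[qb] for pb, qb in zip(pre_bands, post_bands)])
    return ReclassificationResult(
        pre=pre, post=post, pre_events=pre_events, post_events=post_events,
        down_events=int((moved_down & event).sum()),
        down_nonevents=int((moved_down & ~event).sum()),
        up_events=int((moved_up & event).sum()),
        up_nonevents=int((moved_up & ~event).sum()),
        events=int(event.sum()), nonevents=int((~event).sum()),
    )


def net_reclassification_index(result: ReclassificationResult) -> float:
    """Binary NRI over the low/intermediate/high bands."""
    if result.events <= 0 or result.nonevents <= 0:
        raise ValueError("NRI requires both events and non-events")
    ev = (result.up_events - result.down_events) / result.events
    ne = (result.down_nonevents - result.up_nonevents) / result.nonevents
    return float(ev + ne)
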