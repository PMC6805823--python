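"""PTP model, risk bands, disease coding and the NRI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cadscore import (DiseaseLevel, PTPModel, ReclassificationResult, RiskClass,
                      UnclassifiableError, assign_disease_level, compute_ptp,
                      net_reclassification_index, ptp_band, reclassification_table,
                      reclassify)

TOY_PTP = PTPModel(intercept=0.0, age=0.0, male=0.0,
                   symptom={"typical": 0.0, "atypical": 0.0, "non_specific": 0.0})


class TestPTP:
    def test_zero_coefficients_give_half(self):
        for sym in ("typical", "atypical", "non_specific"):
            assert compute_ptp(TOY_PTP, 60.0, "female", sym) == 0.5

    def test_intercept_only_closed_form(self):
        m = PTPModel(intercept=-2.0, age=0.0, male=0.0, symptom={"typical": 0.0})
        assert compute_ptp(m, 50.0, "female", "typical") == pytest.approx(
            1.0 / (1.0 + np.exp(2.0)), abs=1e-12)

    def test_strictly_increasing_in_age(self):
        m = PTPModel(intercept=-3.0, age=0.05, male=0.0, symptom={"atypical": 0.0})
        vals = [compute_ptp(m, a, "male", "atypical") for a in (40, 50, 60, 70)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_unconfigured_symptom_rejected(self):
        with pytest.raises(KeyError):
            compute_ptp(TOY_PTP, 60.0, "male", "none")

    def test_default_model_covers_all_symptoms(self):
        m = PTPModel.default()
        for sym in ("typical", "atypical", "non_specific", "none"):
            assert 0.0 < compute_ptp(m, 58.0, "female", sym) < 1.0


class TestBands:
    @pytest.mark.parametrize("ptp,band", [
        (0.149, RiskClass.low),
        (0.15, RiskClass.intermediate),   # edges belong to intermediate
        (0.85, RiskClass.intermediate),
        (0.851, RiskClass.high),
        (0.86, RiskClass.high),
        (0.0, RiskClass.low),
        (1.0, RiskClass.high),
    ])
    def test_band_edges(self, ptp, band):
        assert ptp_band(ptp) is band

    def test_out_of_range_rejected(self):
        for v in (-0.01, 1.01):
            with pytest.raises(ValueError):
                ptp_band(v)


class TestDiseaseLevel:
    def test_clean_imaging_is_non_cad(self):
        assert assign_disease_level(cacs=0, cta_stenosis_pct=None) is DiseaseLevel.non_cad

    def test_calcium_without_significant_stenosis_is_mild(self):
        assert assign_disease_level(cacs=120, cta_stenosis_pct=30) is DiseaseLevel.mild_cad

    def test_cag_stenosis_50pct_is_significant(self):
        assert assign_disease_level(cacs=400, cta_stenosis_pct=70,
                                    cag_stenosis_pct=60) is DiseaseLevel.significant_cad
        assert assign_disease_level(cag_stenosis_pct=50) is DiseaseLevel.significant_cad
        assert assign_disease_level(cacs=0, cag_stenosis_pct=49) is DiseaseLevel.mild_cad

    def test_no_modality_unclassifiable(self):
        with pytest.raises(UnclassifiableError):
            assign_disease_level()


class TestReclassify:
    @pytest.mark.parametrize("pre,score,post", [
        (RiskClass.intermediate, 18, RiskClass.low),
        (RiskClass.intermediate, 20, RiskClass.low),   # <= 20 moves down
        (RiskClass.intermediate, 21, RiskClass.intermediate),
        (RiskClass.low, 95, RiskClass.low),            # never moved
        (RiskClass.high, 3, RiskClass.high),
    ])
    def test_scheme(self, pre, score, post):
        assert reclassify(pre, score) is post


def toy_cohort(rows):
    """rows: (ptp, cad_score, is_event)"""
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(len(rows))],
        "ptp": [r[0] for r in rows],
        "cad_score": [r[1] for r in rows],
        "disease_level": ["significant_cad" if r[2] else "non_cad" for r in rows],
    })


class TestReclassificationTable:
    def test_four_patient_hand_enumeration(self):
        df = toy_cohort([(0.5, 10, True), (0.5, 10, False),
                         (0.5, 30, False), (0.1, 50, False)])
        res = reclassification_table(df)
        assert res.post["low"] == 3
        assert res.down_events == 1 and res.down_nonevents == 1
        assert res.pre["low"] == 1 and res.pre["intermediate"] == 3

    def test_no_movement_identity(self):
        df = toy_cohort([(0.5, 30, True), (0.5, 40, False), (0.1, 5, False)])
        res = reclassification_table(df)
        assert res.pre == res.post

    def test_all_low_identity(self):
        df = toy_cohort([(0.05, 10, True), (0.1, 90, False)])
        res = reclassification_table(df)
        assert res.pre == res.post == {"low": 2, "intermediate": 0, "high": 0}

    def test_missing_fields_listed(self):
        df = toy_cohort([(0.5, 10, True), (np.nan, 10, False)])
        with pytest.raises(ValueError, match="P1"):
            reclassification_table(df)

    @given(st.lists(st.tuples(st.floats(0.0, 1.0), st.integers(0, 99), st.booleans()),
                    min_size=2, max_size=60).filter(
                        lambda rows: any(r[2] for r in rows) and any(not r[2] for r in rows)))
    def test_down_only_invariants(self, rows):
        res = reclassification_table(toy_cohort(rows))
        assert res.up_events == 0 and res.up_nonevents == 0
        assert res.post["low"] >= res.pre["low"]
        assert res.post["high"] == res.pre["high"]
        assert res.down_events <= res.events
        nri = net_reclassification_index(res)
        assert -2.0 <= nri <= 2.0
        # permutation invariance
        perm = toy_cohort(rows[::-1])
        assert reclassification_table(perm).as_dict() == res.as_dict()


class TestNRI:
    def _result(self, down_events, down_nonevents, events, nonevents):
        return ReclassificationResult(
            pre={}, post={}, pre_events={}, post_events={},
            down_events=down_events, down_nonevents=down_nonevents,
            up_events=0, up_nonevents=0, events=events, nonevents=nonevents)

    def test_published_movement_counts(self):
        """472 of 1673 symptomatic patients move down, 21 of them events:
        NRI = -21/211 + 451/1462 = 0.209."""
        res = self._result(down_events=28 - 7, down_nonevents=472 - 21,
                           events=58 + 153, nonevents=1673 - 211)
        assert round(net_reclassification_index(res), 3) == 0.209

    def test_no_movement_zero(self):
        assert net_reclassification_index(self._result(0, 0, 10, 90)) == 0.0

    def test_all_nonevents_down_is_one(self):
        assert net_reclassification_index(self._result(0, 90, 10, 90)) == 1.0

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            net_reclassification_index(self._result(0, 5, 0, 90))
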