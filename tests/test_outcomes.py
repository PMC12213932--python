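"""Cardiovascular sub-score, composite deterioration labelling, organ-dysfunction totals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import label_minute_scan
from pedews.features import VasoactiveDoses
from pedews.outcomes import (cv_subscore, cv_subscore_series, label_window,
                             psofa_total, PSofaVector, secondary_labels)


class TestCvSubscore:
    def test_normotensive_no_support(self, refs):
        assert cv_subscore(70.0, 30.0, VasoactiveDoses(), refs.psofa_map) == 0

    def test_hypotension_without_vasoactives(self, refs):
        # 30-month-old: MAP lower limit 62 mmHg
        assert cv_subscore(55.0, 30.0, VasoactiveDoses(), refs.psofa_map) == 1

    def test_milrinone_counts_as_dobutamine(self, refs):
        # the modification: any milrinone alone scores 2, like dobutamine
        assert cv_subscore(70.0, 30.0, VasoactiveDoses(milrinone=0.5), refs.psofa_map) == 2
        assert cv_subscore(70.0, 30.0, VasoactiveDoses(dobutamine=5.0), refs.psofa_map) == 2

    @pytest.mark.parametrize("doses, expected", [
        (VasoactiveDoses(dopamine=3.0), 2),
        (VasoactiveDoses(dopamine=8.0), 3),
        (VasoactiveDoses(epinephrine=0.05), 3),
        (VasoactiveDoses(norepinephrine=0.1), 3),
        (VasoactiveDoses(dopamine=20.0), 4),
        (VasoactiveDoses(epinephrine=0.2), 4),
        (VasoactiveDoses(vasopressin=0.0005), 4),
    ])
    def test_dose_bands(self, refs, doses, expected):
        assert cv_subscore(70.0, 30.0, doses, refs.psofa_map) == expected

    def test_missing_map_no_drugs_is_missing(self, refs):
        assert np.isnan(cv_subscore(float("nan"), 30.0, VasoactiveDoses(), refs.psofa_map))

    @given(st.floats(min_value=0, max_value=25), st.floats(min_value=0, max_value=2))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_each_dose(self, refs, dop, extra):
        base = cv_subscore(70.0, 30.0, VasoactiveDoses(dopamine=dop), refs.psofa_map)
        more = cv_subscore(70.0, 30.0, VasoactiveDoses(dopamine=dop + extra), refs.psofa_map)
        assert more >= base

    def test_adding_milrinone_never_lowers(self, refs):
        for doses in (VasoactiveDoses(), VasoactiveDoses(dopamine=8.0),
                      VasoactiveDoses(epinephrine=0.2)):
            with_mil = VasoactiveDoses(**{**doses.__dict__, "milrinone": 0.4})
            assert (cv_subscore(70.0, 30.0, with_mil, refs.psofa_map)
                    >= cv_subscore(70.0, 30.0, doses, refs.psofa_map))

    def test_series_matches_scalar(self, refs):
        rng = np.random.default_rng(1)
        n = 200
        mapv = rng.uniform(40, 90, n)
        doses = {"dopamine": rng.choice([0, 3, 8, 20], n).astype(float),
                 "epinephrine": rng.choice([0.0, 0.05, 0.2], n)}
        series = cv_subscore_series(mapv, doses, 30.0, refs.psofa_map)
        for i in range(n):
            scalar = cv_subscore(mapv[i], 30.0,
                                 VasoactiveDoses(dopamine=doses["dopamine"][i],
                                                 epinephrine=doses["epinephrine"][i]),
                                 refs.psofa_map)
            assert series[i] == scalar


def _flat(n, v=0.0):
    return np.full(n, v)


class TestLabelWindow:
    L, H = 360, 720

    def test_death_in_horizon(self):
        n = 24 * 60
        lab = label_window(600, self.L, self.H, _flat(n), _flat(n, 1.0), n,
                           death_min=600 + 180)
        assert lab.label == 1 and lab.trigger == "death"

    def test_lactate_high_but_not_increasing(self):
        n = 24 * 60
        lac = np.full(n, 2.2)
        lac[:600] = 2.5  # lookback maximum 2.5 exceeds everything later
        lab = label_window(600, self.L, self.H, _flat(n), lac, n)
        assert lab.label == 0 and lab.trigger == "none"

    def test_lactate_rise_above_threshold(self):
        n = 24 * 60
        lac = np.full(n, 1.0)
        lac[800:] = 2.4
        lab = label_window(600, self.L, self.H, _flat(n), lac, n)
        assert lab.label == 1 and lab.trigger == "lactate" and lab.trigger_min == 800

    def test_cv_rise_over_lookback_max(self):
        n = 24 * 60
        cv = np.zeros(n)
        cv[300:500] = 1.0   # lookback max is 1
        cv[900:] = 2.0      # horizon reaches 2: a rise
        lab = label_window(600, self.L, self.H, cv, _flat(n, 1.0), n)
        assert lab.label == 1 and lab.trigger == "cv_rise" and lab.trigger_min == 900

    def test_cv_equal_to_lookback_max_is_not_a_rise(self):
        n = 24 * 60
        cv = np.zeros(n)
        cv[500:] = 2.0  # already at 2 before the anchor
        lab = label_window(600, self.L, self.H, cv, _flat(n, 1.0), n)
        assert lab.label == 0

    def test_new_ecmo_fires(self):
        n = 24 * 60
        lab = label_window(600, self.L, self.H, _flat(n), _flat(n, 1.0), n, ecmo_min=700.0)
        assert lab.label == 1 and lab.trigger == "ecmo"

    def test_horizon_truncated_at_discharge(self):
        n = 700  # discharge 100 minutes after the anchor
        cv = np.zeros(n)
        lab = label_window(600, self.L, self.H, cv, _flat(n, 1.0), n)
        assert lab.label == 0

    def test_at_anchor_baseline_mode(self):
        n = 24 * 60
        cv = np.zeros(n)
        cv[300:400] = 2.0  # an old peak inside the lookback [240, 600]
        cv[900:] = 1.0
        strict = label_window(600, self.L, self.H, cv, _flat(n, 1.0), n, baseline="lookback_max")
        lenient = label_window(600, self.L, self.H, cv, _flat(n, 1.0), n, baseline="at_anchor")
        assert strict.label == 0      # 1 does not exceed the lookback max of 2
        assert lenient.label == 1     # but it does exceed the value at the anchor (0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_minute_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(400, 2000))
        cv = rng.choice([0, 0, 0, 1, 2, 3, 4], n).astype(float)
        cv[rng.uniform(size=n) < 0.1] = np.nan
        lac = np.round(rng.lognormal(0.2, 0.5, n), 1)
        lac[rng.uniform(size=n) < 0.3] = np.nan
        death = float(rng.integers(n - 100, n + 500)) if rng.uniform() < 0.3 else None
        ecmo = float(rng.integers(100, n)) if rng.uniform() < 0.2 else None
        t = int(rng.integers(360, n))
        got = label_window(t, 360, 720, cv, lac, n, death, ecmo)
        want = label_minute_scan(t, 360, 720, cv, lac, n, death, ecmo)
        assert (got.label, got.trigger, got.trigger_min) == want


class TestPsofaTotal:
    def test_all_normal_scores_zero(self, refs):
        v = psofa_total({"sf_ratio": 450, "platelets": 300, "bilirubin": 8,
                         "gcs": 15, "creatinine": 30, "map": 75},
                        age_months=30, bands=refs.psofa_bands, map_thresholds=refs.psofa_map)
        assert v.total == 0

    def test_single_failing_system_additivity(self, refs):
        v = psofa_total({"sf_ratio": 450, "platelets": 10, "bilirubin": 8,
                         "gcs": 15, "creatinine": 30, "map": 75},
                        age_months=30, bands=refs.psofa_bands, map_thresholds=refs.psofa_map)
        assert v.coagulation == 4 and v.total == 4

    def test_worked_vector(self, refs):
        # platelets 80 -> 2; bilirubin 40 umol/l -> 2; creatinine 150 umol/l
        # at 30 months (band edge 141) -> 3; other systems normal
        v = psofa_total({"sf_ratio": 450, "platelets": 80, "bilirubin": 40,
                         "gcs": 15, "creatinine": 150, "map": 75},
                        age_months=30, bands=refs.psofa_bands, map_thresholds=refs.psofa_map)
        assert v == PSofaVector(respiratory=0, coagulation=2, hepatic=2,
                                cardiovascular=0, neurological=0, renal=3)
        assert v.total == 7

    def test_respiratory_capped_without_ventilation(self, refs):
        low_sf = {"sf_ratio": 100, "map": 75, "gcs": 15}
        unvented = psofa_total(low_sf, 30, refs.psofa_bands, refs.psofa_map, vent_level=0)
        vented = psofa_total(low_sf, 30, refs.psofa_bands, refs.psofa_map, vent_level=3)
        assert unvented.respiratory == 2 and vented.respiratory == 4

    def test_missing_inputs_score_zero(self, refs):
        v = psofa_total({}, 30, refs.psofa_bands, refs.psofa_map)
        assert v.total == 0


class TestSecondaryLabels:
    def test_death_within_48h(self):
        out = secondary_labels(100, death_min=100 + 47 * 60, discharge_min=100 + 47 * 60)
        assert out == {"death_within_48h": 1, "discharge_within_7d": 0}

    def test_discharge_within_7d(self):
        out = secondary_labels(0, death_min=None, discharge_min=6 * 24 * 60)
        assert out == {"death_within_48h": 0, "discharge_within_7d": 1}
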