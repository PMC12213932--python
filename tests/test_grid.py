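"""Minute grid, gap-limited interpolation, lab carry-forward, imputation, scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pedews import grid as G
from pedews.errors import ConfigurationError, NotFittedError


def _series(obs: dict[int, float], n: int, feature: str = "hr") -> G.GriddedSeries:
    minutes = np.array(list(obs), float)
    values = np.array(list(obs.values()), float)
    return G.to_minute_grid(minutes, values, n, feature)


class TestToMinuteGrid:
    def test_same_minute_mean(self):
        s = G.to_minute_grid([10.2, 10.8], [118.0, 122.0], 20, "hr")
        assert s.values[10] == 120.0 and s.provenance[10] == G.OBSERVED

    def test_single_observation_identity(self):
        s = _series({5: 99.0}, 10)
        assert s.values[5] == 99.0
        assert (s.provenance == G.OBSERVED).sum() == 1

    def test_observation_count_preserved(self):
        rng = np.random.default_rng(0)
        minutes = rng.choice(360, size=9, replace=False)
        s = G.to_minute_grid(minutes, rng.normal(100, 5, 9), 360, "hr")
        assert (s.provenance == G.OBSERVED).sum() == 9

    def test_out_of_admission_dropped(self):
        log = []
        s = G.to_minute_grid([-3, 5, 400], [1.0, 2.0, 3.0], 60, "hr", log=log)
        assert (s.provenance == G.OBSERVED).sum() == 1
        assert log and "dropped 2" in log[0]


class TestInterpolate:
    def test_linear_midpoint(self):
        s = G.interpolate(_series({0: 100.0, 60: 160.0}, 61))
        assert s.values[30] == pytest.approx(130.0)
        assert s.provenance[30] == G.INTERPOLATED

    def test_gap_over_limit_left_missing(self):
        s = G.interpolate(_series({0: 100.0, 120: 160.0}, 121))
        interior = s.values[1:120]
        assert np.isnan(interior).all() and len(interior) == 119

    def test_gap_of_exactly_90_filled(self):
        s = G.interpolate(_series({0: 100.0, 90: 190.0}, 91))
        assert not np.isnan(s.values[1:90]).any()
        assert s.values[45] == pytest.approx(145.0)

    def test_no_extrapolation(self):
        s = G.interpolate(_series({30: 100.0}, 120))
        assert np.isnan(s.values[0]) and np.isnan(s.values[119])

    def test_idempotent_and_observed_untouched(self):
        s0 = _series({0: 100.0, 45: 90.0, 300: 80.0}, 400)
        s1 = G.interpolate(s0)
        s2 = G.interpolate(s1)
        np.testing.assert_array_equal(s1.provenance, s2.provenance)
        np.testing.assert_allclose(s1.values, s2.values, equal_nan=True)
        assert s1.values[45] == 90.0 and s1.provenance[45] == G.OBSERVED


class TestCarryForward:
    def test_carry_within_four_days(self):
        n = 6 * 24 * 60
        s = G.carry_forward_labs(_series({0: 2.5}, n))
        assert s.values[3 * 24 * 60] == 2.5           # day 3: still carried
        assert np.isnan(s.values[5 * 24 * 60])        # day 5: expired
        assert s.provenance[60] == G.CARRIED

    def test_step_semantics_no_interpolation(self):
        n = 3 * 24 * 60
        s = G.carry_forward_labs(_series({0: 1.0, 24 * 60: 3.0}, n))
        assert s.values[12 * 60] == 1.0               # between labs: earlier value holds
        assert s.values[30 * 60] == 3.0


class TestImpute:
    @pytest.fixture()
    def policy(self):
        return G.ImputationPolicy({
            "hr": ("age_stratified_median", None),
            "spo2": ("global_median", None),
            "vent_level": ("assume_absent", 0.0),
        })

    def test_assume_absent_zero_support(self, policy):
        s = G.GriddedSeries("vent_level", np.full(10, np.nan), np.zeros(10, np.uint8))
        out = G.impute(s, policy, age_days=400, cohort_medians={})
        assert (out.values == 0.0).all() and (out.provenance == G.IMPUTED).all()

    def test_age_stratified_median(self, policy):
        medians = {"hr": np.array([150, 130, 115, 100, 85, 75], float)}
        s = G.GriddedSeries("hr", np.full(5, np.nan), np.zeros(5, np.uint8))
        out = G.impute(s, policy, age_days=800, cohort_medians=medians)  # 2-5 y band
        assert (out.values == 100.0).all()

    def test_global_median(self, policy):
        s = G.GriddedSeries("spo2", np.array([97.0, np.nan]), np.array([1, 0], np.uint8))
        out = G.impute(s, policy, 100, {"spo2": 96.0})
        assert out.values[1] == 96.0 and out.values[0] == 97.0

    def test_full_coverage_after_impute(self, policy):
        rng = np.random.default_rng(3)
        vals = np.where(rng.uniform(size=500) < 0.3, rng.normal(100, 5, 500), np.nan)
        prov = np.where(np.isnan(vals), 0, 1).astype(np.uint8)
        out = G.impute(G.GriddedSeries("hr", vals, prov), policy, 30,
                       {"hr": np.full(6, 120.0)})
        assert not np.isnan(out.values).any()

    def test_unconfigured_feature_raises(self, policy):
        s = G.GriddedSeries("lactate", np.full(3, np.nan), np.zeros(3, np.uint8))
        with pytest.raises(ConfigurationError, match="lactate"):
            G.impute(s, policy, 100, {})


class TestPercentileScaler:
    def test_midrank_convention(self):
        sc = G.PercentileScaler().fit({"x": np.array([2.0, 2.0, 4.0, 8.0])})
        assert sc.transform_column("x", 4.0) == pytest.approx(0.625)  # (2 + 0.5)/4

    def test_rank_of_median_query(self):
        sc = G.PercentileScaler().fit({"x": np.arange(1.0, 101.0)})
        assert sc.transform_column("x", 50.0) == pytest.approx(0.5, abs=0.0051)

    def test_clipping_beyond_training_range(self):
        sc = G.PercentileScaler().fit({"x": np.arange(10.0)})
        assert sc.transform_column("x", -5.0) == 0.0
        assert sc.transform_column("x", 99.0) == 1.0

    def test_apply_before_fit_raises(self):
        with pytest.raises(NotFittedError):
            G.PercentileScaler().transform_column("x", 1.0)

    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=5, max_size=40),
           st.floats(min_value=-100, max_value=100), st.floats(min_value=-100, max_value=100))
    @settings(max_examples=50, deadline=None)
    def test_order_preserving(self, train, a, b):
        sc = G.PercentileScaler().fit({"x": np.array(train)})
        lo, hi = sorted((a, b))
        assert sc.transform_column("x", lo) <= sc.transform_column("x", hi)

    def test_training_data_roundtrip_uniform(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(1.0, 0.8, 2000)
        sc = G.PercentileScaler().fit({"x": x})
        u = sc.transform_column("x", x)
        hist, _ = np.histogram(u, bins=10, range=(0, 1))
        assert hist.min() > 150  # ~200 expected per bin: rank transform is uniform
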