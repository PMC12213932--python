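"""Window cutting, summary statistics, ablations, resampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import ols_normal_equations
from pedews.grid import OBSERVED, GriddedSeries
from pedews.windows import (FeatureRegistry, WindowSpec, ablate, resample,
                            summarise, summarise_windows, window_anchors)


class TestWindowAnchors:
    def test_admission_shorter_than_lookback_excluded(self):
        assert len(window_anchors(5 * 60, WindowSpec(lookback_h=6))) == 0

    def test_hourly_anchor_enumeration(self):
        anchors = window_anchors(12 * 60, WindowSpec(lookback_h=6, stride_min=60))
        np.testing.assert_array_equal(anchors, np.arange(360, 721, 60))
        assert len(anchors) == 7

    def test_exact_length_admission_single_sample(self):
        anchors = window_anchors(3 * 60, WindowSpec(lookback_h=3))
        np.testing.assert_array_equal(anchors, [180])

    @given(st.integers(min_value=0, max_value=20000), st.integers(min_value=1, max_value=240))
    @settings(max_examples=200, deadline=None)
    def test_count_formula_matches_enumeration(self, los_min, stride):
        spec = WindowSpec(lookback_h=6, stride_min=stride)
        L = spec.lookback_min
        expected = max(0, (los_min - L) // stride + 1) if los_min >= L else 0
        assert len(window_anchors(los_min, spec)) == expected


class TestSummarise:
    def test_exact_line(self):
        # values 1,2,3 one hour apart: slope 1/h and a perfect fit
        vals = np.full(121, np.nan)
        vals[0], vals[60], vals[120] = 1.0, 2.0, 3.0
        vals = np.interp(np.arange(121), [0, 60, 120], [1, 2, 3])
        s = summarise(vals, np.zeros(121, bool), lookback_h=2 + 1 / 60)
        assert s.mean == pytest.approx(2.0)
        assert s.slope == pytest.approx(1.0)
        assert s.r2 == pytest.approx(1.0)

    def test_three_point_line_stats(self):
        s = summarise([1.0, 2.0, 3.0], [True, True, True], lookback_h=3.0, period_min=60)
        assert (s.mean, s.sd, s.slope, s.r2) == pytest.approx((2.0, 1.0, 1.0, 1.0))
        assert s.freq == pytest.approx(1.0)

    def test_constant_series_degenerate_conventions(self):
        s = summarise(np.full(60, 5.0), np.zeros(60, bool), lookback_h=1.0)
        assert (s.mean, s.sd, s.slope, s.r2) == (5.0, 0.0, 0.0, 0.0)

    def test_hand_computed_ols(self):
        # 1, 3, 2 at 0/60/120 min: slope 0.5/h, R^2 = 0.25 by the normal equations
        s = summarise([1.0, 3.0, 2.0], [True] * 3, lookback_h=3.0, period_min=60)
        assert s.slope == pytest.approx(0.5)
        assert s.r2 == pytest.approx(0.25)

    def test_single_point(self):
        s = summarise([7.0], [True], lookback_h=1.0)
        assert (s.slope, s.r2, s.sd) == (0.0, 0.0, 0.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 240))
        vals = rng.normal(rng.uniform(-50, 50), rng.uniform(0.1, 20), n)
        s = summarise(vals, np.ones(n, bool), lookback_h=n / 60.0)
        slope, r2 = ols_normal_equations(vals)
        assert s.slope == pytest.approx(slope, abs=1e-9)
        assert s.r2 == pytest.approx(r2, abs=1e-9)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_time_reversal_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(10, 3, 90)
        fwd = summarise(vals, np.ones(90, bool), lookback_h=1.5)
        rev = summarise(vals[::-1], np.ones(90, bool), lookback_h=1.5)
        assert rev.mean == pytest.approx(fwd.mean)
        assert rev.sd == pytest.approx(fwd.sd)
        assert rev.slope == pytest.approx(-fwd.slope, abs=1e-9)


class TestSummariseWindows:
    def test_batch_equals_single_window(self):
        rng = np.random.default_rng(9)
        n = 24 * 60
        vals = rng.normal(100, 8, n)
        prov = np.where(rng.uniform(size=n) < 0.05, OBSERVED, 2).astype(np.uint8)
        series = GriddedSeries("hr", vals, prov)
        spec = WindowSpec(lookback_h=6, stride_min=60)
        anchors = window_anchors(n, spec)
        batch = summarise_windows(series, anchors, spec)
        for i, t in enumerate(anchors):
            w = slice(t - spec.lookback_min, t)
            single = summarise(vals[w], prov[w] == OBSERVED, spec.lookback_h)
            np.testing.assert_allclose(batch[i], single.as_tuple(), atol=1e-9)

    def test_frequency_counts_only_observed_minutes(self):
        vals = np.ones(360)
        prov = np.full(360, 2, np.uint8)  # everything interpolated
        prov[[0, 100, 200]] = OBSERVED
        series = GriddedSeries("hr", vals, prov)
        spec = WindowSpec(lookback_h=6)
        out = summarise_windows(series, np.array([360]), spec)
        assert out[0, 4] == pytest.approx(3 / 6.0)  # interpolation does not inflate frequency


class TestResample:
    def test_thinning_counts(self):
        s = GriddedSeries("hr", np.arange(360.0), np.ones(360, np.uint8))
        assert resample(s, 60).n_minutes == 6
        assert resample(s, 15).n_minutes == 24

    def test_constant_series_summary_invariant(self):
        s = GriddedSeries("hr", np.full(360, 42.0), np.ones(360, np.uint8))
        thin = resample(s, 15)
        summ = summarise(thin.values, thin.provenance == OBSERVED, 6.0, period_min=15)
        assert (summ.mean, summ.sd) == (42.0, 0.0)


@pytest.fixture()
def toy_matrix():
    cols = {}
    rows = []
    for f in ("hr", "map"):
        for stat in ("mean", "sd", "slope", "r2", "freq", "latest"):
            cols[f"{f}__{stat}"] = np.arange(3.0)
            rows.append({"column": f"{f}__{stat}", "feature": f, "stat": stat, "kind": "timeseries"})
    cols["lactate__latest"] = np.arange(3.0)
    rows.append({"column": "lactate__latest", "feature": "lactate", "stat": "latest", "kind": "lab"})
    cols["age_years"] = np.arange(3.0)
    rows.append({"column": "age_years", "feature": "age_years", "stat": "static", "kind": "static"})
    return pd.DataFrame(cols), FeatureRegistry(pd.DataFrame(rows))


class TestAblate:
    def test_no_trend_drops_slope_and_r2(self, toy_matrix):
        X, reg = toy_matrix
        out, _ = ablate(X, reg, "no_trend")
        assert X.shape[1] - out.shape[1] == 4  # slope and r2 for each of 2 series

    def test_no_frequency(self, toy_matrix):
        X, reg = toy_matrix
        out, _ = ablate(X, reg, "no_frequency")
        assert not [c for c in out.columns if c.endswith("__freq")]

    def test_latest_only(self, toy_matrix):
        X, reg = toy_matrix
        out, _ = ablate(X, reg, "latest_only")
        assert set(out.columns) == {"hr__latest", "map__latest", "lactate__latest", "age_years"}

    def test_topk_exact_count(self, toy_matrix):
        X, reg = toy_matrix
        ranking = list(X.columns)[::-1]
        out, _ = ablate(X, reg, "topk", k=5, ranking=ranking)
        assert out.shape[1] == 5 and list(out.columns)[0] in ranking[:5]

    def test_topk_exceeding_keeps_all_with_warning(self, toy_matrix):
        X, reg = toy_matrix
        with pytest.warns(UserWarning):
            out, _ = ablate(X, reg, "topk", k=99, ranking=list(X.columns))
        assert out.shape[1] == X.shape[1]
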