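"""Patient-level splitting, tuning, comparator construction, prediction contract."""

import numpy as np
import pandas as pd
import pytest

from pedews.errors import RegistryMismatchError
from pedews.evaluation import pr_metrics
from pedews.models import (PSOFA_COMPONENTS, RiskModel, SearchConfig,
                           fit_psofa_comparator, predict, split_patients,
                           tune_and_fit)


class TestSplitPatients:
    def test_default_85_15(self):
        plan = split_patients([f"p{i}" for i in range(100)], seed=0)
        assert len(plan.patients("train")) == 85
        assert len(plan.patients("test")) == 15

    def test_deterministic_under_seed(self):
        ids = [f"p{i}" for i in range(50)]
        a = split_patients(ids, seed=7)
        b = split_patients(ids, seed=7)
        pd.testing.assert_series_equal(a.assignments.sort_index(), b.assignments.sort_index())

    def test_windows_inherit_patient_split(self):
        plan = split_patients([f"p{i}" for i in range(20)], seed=1)
        windows = pd.Series(["p3"] * 30)  # one patient with 30 windows
        splits = plan.window_split(windows)
        assert splits.nunique() == 1

    def test_three_way_fractions(self):
        plan = split_patients([f"p{i}" for i in range(100)],
                              {"train": 0.70, "val": 0.15, "test": 0.15}, seed=0)
        sizes = {s: len(plan.patients(s)) for s in ("train", "val", "test")}
        assert sizes == {"train": 70, "val": 15, "test": 15}

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_patients(["a", "b", "c"], {"train": 1.0, "test": 0.0}, seed=0)


def _separable_toy(n=200, seed=0):
    """Positives have feature x=1, negatives x=0, plus a noise column."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = pd.DataFrame({"x": y.astype(float), "noise": rng.normal(size=n)})
    groups = np.array([f"p{i % 40}_{yi}" for i, yi in enumerate(y)])
    return X, y, groups


class TestTuneAndFit:
    def test_budget_one_returns_single_configuration(self):
        X, y, groups = _separable_toy()
        model = tune_and_fit(X, y, groups, "logistic_l2", SearchConfig(budget=1, seed=0))
        assert model.estimator is not None and model.best_params is not None

    @pytest.mark.parametrize("family", ["gbdt", "logistic_l2"])
    def test_separable_toy_perfect_auprc(self, family):
        X, y, groups = _separable_toy()
        model = tune_and_fit(X, y, groups, family, SearchConfig(budget=2, seed=0))
        held_X, held_y, _ = _separable_toy(seed=123)
        assert pr_metrics(predict(model, held_X), held_y).auprc == pytest.approx(1.0)

    def test_search_is_deterministic(self):
        X, y, groups = _separable_toy()
        cfg = SearchConfig(budget=3, seed=5)
        a = tune_and_fit(X, y, groups, "logistic_l2", cfg)
        b = tune_and_fit(X, y, groups, "logistic_l2", cfg)
        assert a.best_params == b.best_params

    def test_near_unpenalised_logistic_approaches_separator(self):
        # two-point toy: boundary must approach the midpoint x=0.5
        X = pd.DataFrame({"x": [0.0, 1.0] * 20})
        y = np.array([0, 1] * 20)
        m = RiskModel("logistic_l2", params={"C": 1e6}).fit(X, y)
        p_mid = m.estimator.predict_proba([[0.5]])[0, 1]
        assert p_mid == pytest.approx(0.5, abs=0.1)
        # the two training points themselves are classified with near certainty
        assert m.estimator.predict_proba([[0.0]])[0, 1] < 0.01
        assert m.estimator.predict_proba([[1.0]])[0, 1] > 0.99


class TestPsofaComparator:
    @pytest.fixture(scope="class")
    def psofa_frame(self):
        rng = np.random.default_rng(0)
        n = 300
        cols = {}
        for c in PSOFA_COMPONENTS:
            cols[f"psofa_{c}__latest"] = rng.integers(0, 5, n).astype(float)
            cols[f"psofa_{c}__mean"] = rng.uniform(0, 4, n)
            cols[f"psofa_{c}__sd"] = rng.uniform(0, 1, n)
        df = pd.DataFrame(cols)
        df["psofa_total__latest"] = sum(df[f"psofa_{c}__latest"] for c in PSOFA_COMPONENTS)
        y = (df["psofa_total__latest"] + rng.normal(0, 2, n) > 10).astype(int)
        return df, y

    @pytest.mark.parametrize("variant, n_cols", [
        ("summary", 1), ("components", 6), ("components_mean_var", 18),
    ])
    def test_predictor_counts(self, psofa_frame, variant, n_cols):
        df, y = psofa_frame
        model = fit_psofa_comparator(variant, "logistic", df, y)
        assert len(model.feature_names) == n_cols

    def test_missing_columns_raise(self, psofa_frame):
        df, y = psofa_frame
        with pytest.raises(RegistryMismatchError):
            fit_psofa_comparator("components", "logistic", df.drop(columns=["psofa_renal__latest"]), y)


class TestPredict:
    @pytest.fixture(scope="class")
    def fitted(self):
        X, y, _ = _separable_toy()
        return RiskModel("gbdt", params={"n_estimators": 30, "max_depth": 2}).fit(X, y), X

    def test_empty_input_empty_output(self, fitted):
        model, X = fitted
        assert len(predict(model, X.iloc[0:0])) == 0

    def test_duplicated_sample_identical_probability(self, fitted):
        model, X = fitted
        dup = pd.concat([X.iloc[[0]], X.iloc[[0]]], ignore_index=True)
        p = predict(model, dup)
        assert p[0] == p[1]

    def test_probabilities_in_unit_interval(self, fitted):
        model, X = fitted
        p = predict(model, X)
        assert (p >= 0).all() and (p <= 1).all()

    def test_registry_mismatch_names_columns(self, fitted):
        model, X = fitted
        bad = X.rename(columns={"noise": "intruder"})
        with pytest.raises(RegistryMismatchError, match="intruder"):
            predict(model, bad)

    def test_monotone_feature_gives_monotone_scores(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 400)
        y = (rng.uniform(size=400) < x).astype(int)  # P(y=1) increasing in x
        X = pd.DataFrame({"x": x})
        model = RiskModel("gbdt", params={"n_estimators": 60, "max_depth": 2}).fit(X, y)
        grid = pd.DataFrame({"x": np.linspace(0.05, 0.95, 10)})
        p = predict(model, grid)
        # allow small local violations from greedy splits; overall trend must rise
        assert p[-1] > p[0] and np.corrcoef(grid["x"], p)[0, 1] > 0.9
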