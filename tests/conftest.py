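"""Shared fixtures: a tiny cohort for unit tests, a full-size trained run.

The full-size fixture is session-scoped and shared by every test that needs
a trained model, so the expensive cohort generation / featurisation /
tuning happens exactly once per session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from pedews import default_config
from pedews.config import PipelineConfig
from pedews.grid import PercentileScaler
from pedews.models import SearchConfig, split_patients, tune_and_fit
from pedews.pipeline import FeaturisedCohort, featurize_cohort, label_cohort
from pedews.references import ReferenceSet
from pedews.synthetic import Cohort, CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def refs() -> ReferenceSet:
    return ReferenceSet.load()


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    return generate_cohort(CohortSpec(n_patients=30, seed=202))


@dataclass
class TrainedRun:
    config: PipelineConfig
    cohort: Cohort
    features: FeaturisedCohort
    labels: pd.DataFrame
    X_train: pd.DataFrame
    X_test: pd.DataFrame
    y_train: np.ndarray
    y_test: np.ndarray
    groups_train: np.ndarray
    gbdt: object
    prevalence_test: float


@pytest.fixture(scope="session")
def trained_run() -> TrainedRun:
    """Default synthetic cohort (500 patients), featurised, split and tuned.

    Search budget is reduced from the default 20 trials to 4 to keep the
    session within its time budget; the searched space is unchanged.
    """
    config = default_config(
        cohort=CohortSpec(n_patients=500, seed=1),
        search=SearchConfig(budget=4, seed=1),
        seed=1,
    )
    cohort = generate_cohort(config.cohort)
    split = split_patients(cohort.demographics["patient_id"], config.fractions, config.seed)
    feat = featurize_cohort(cohort, config, set(split.patients("train")))
    labels = label_cohort(feat, config)
    is_train = (split.window_split(feat.meta["patient_id"]) == "train").to_numpy()
    scaler = PercentileScaler().fit(feat.X[is_train])
    Xs = scaler.transform(feat.X)
    y = labels["label"].to_numpy()
    groups = feat.meta["patient_id"].to_numpy()
    gbdt = tune_and_fit(Xs[is_train], y[is_train], groups[is_train], "gbdt",
                        config.search, seed=config.seed)
    return TrainedRun(
        config=config, cohort=cohort, features=feat, labels=labels,
        X_train=Xs[is_train], X_test=Xs[~is_train],
        y_train=y[is_train], y_test=y[~is_train],
        groups_train=groups[is_train], gbdt=gbdt,
        prevalence_test=float(y[~is_train].mean()),
    )
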