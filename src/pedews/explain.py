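"""Model interpretation: importance rankings, additive attributions, timelines.

Two complementary views are produced for a fitted risk model: the tree
ensemble's internal (gain-based) feature importance, and per-prediction
additive attributions in model-margin (log-odds) units. Attributions are
decision-path contributions: walking each tree from root to leaf, the
change in node value at every split is credited to the split feature, so
``base + sum(contributions) == margin`` holds exactly for every sample
(local accuracy). Mean absolute contribution per feature gives the global
attribution-importance ordering. For the linear (logistic) family the
attribution is the exact linear decomposition ``coef * x`` about the
intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression

from .errors import RegistryMismatchError
from .models import RiskModel, predict

__all__ = ["Attribution", "internal_importance", "attribute", "patient_timeline"]


@dataclass
class Attribution:
    """Additive per-feature contributions in margin (log-odds) units."""

    feature_names: list[str]
    base: float
    contributions: np.ndarray = field(repr=False)  # (n_samples, n_features)
    margins: np.ndarray = field(repr=False)        # model decision_function

    @property
    def residuals(self) -> np.ndarray:
        """Local-accuracy residual per sample; ~0 by construction."""
        return self.margins - (self.base + self.contributions.sum(axis=1))

    def global_importance(self) -> pd.DataFrame:
        mean_abs = np.abs(self.contributions).mean(axis=0)
        return (pd.DataFrame({"feature": self.feature_names, "mean_abs_contribution": mean_abs})
                .sort_values("mean_abs_contribution", ascending=False, ignore_index=True))


def internal_importance(model: RiskModel) -> pd.DataFrame:
    """Gain-based importance of the fitted tree ensemble, descending.

    This ranking is the one consumed by the top-k feature ablation.
    """
    est = model.estimator
    if not isinstance(est, GradientBoostingClassifier):
        raise RegistryMismatchError("internal importance requires the tree (gbdt) family")
    gains = est.feature_importances_
    return (pd.DataFrame({"feature": model.feature_names, "gain": gains})
            .sort_values("gain", ascending=False, ignore_index=True))


def _tree_path_contributions(tree, X: np.ndarray, contrib: np.ndarray, scale: float) -> float:
    """Accumulate decision-path contributions for one regression tree.

    Returns the tree's root value (needed for the ensemble base). Node
    values are the tree's training-mean targets; the value change across
    each split is credited to the split feature.
    """
    left, right = tree.children_left, tree.children_right
    feat, thresh = tree.feature, tree.threshold
    value = tree.value.reshape(-1)
    node = np.zeros(len(X), dtype=np.int64)
    active = left[node] != -1
    while active.any():
        idx = np.flatnonzero(active)
        f = feat[node[idx]]
        go_left = X[idx, f] <= thresh[node[idx]]
        child = np.where(go_left, left[node[idx]], right[node[idx]])
        contrib[idx, f] += scale * (value[child] - value[node[idx]])
        node[idx] = child
        active[idx] = left[child] != -1
    return float(value[0])


def attribute(model: RiskModel, X: pd.DataFrame) -> Attribution:
    """Additive attributions for every sample of ``X``.

    Tree family: decision-path contributions summed over the ensemble with
    the learning rate applied; base = prior log-odds + learning_rate *
    sum of root values. Linear family: coef * x about the intercept.
    """
    if model.estimator is None or model.feature_names is None:
        raise RegistryMismatchError("model is not fitted")
    if list(X.columns) != model.feature_names:
        raise RegistryMismatchError("feature registry mismatch between model and samples")
    Xa = X.to_numpy(float)
    est = model.estimator
    if isinstance(est, LogisticRegression):
        coef = est.coef_.reshape(-1)
        contrib = Xa * coef[None, :]
        base = float(est.intercept_[0])
        margins = est.decision_function(Xa)
        return Attribution(model.feature_names, base, contrib, margins)
    if not isinstance(est, GradientBoostingClassifier):
        raise RegistryMismatchError(f"no attribution rule for estimator {type(est).__name__}")
    contrib = np.zeros_like(Xa)
    root_sum = 0.0
    for stage in est.estimators_.reshape(-1):
        root_sum += _tree_path_contributions(stage.tree_, Xa, contrib, est.learning_rate)
    prior = est.init_.class_prior_[1]
    base = float(np.log(prior / (1.0 - prior)) + est.learning_rate * root_sum)
    margins = est.decision_function(Xa)
    return Attribution(model.feature_names, base, contrib, margins)


def patient_timeline(
    model: RiskModel, X_admission: pd.DataFrame, anchors_min: np.ndarray, k: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rolling risk over one admission with per-anchor top-k drivers.

    Returns (timeline, drivers): timeline has one row per anchor with the
    predicted deterioration probability; drivers lists, per anchor, the k
    largest-|contribution| features with their input values and
    contributions (margin units). An admission shorter than the lookback
    yields empty frames.
    """
    anchors_min = np.asarray(anchors_min, np.int64)
    if len(X_admission) == 0:
        cols = ["anchor_min", "probability"]
        return pd.DataFrame(columns=cols), pd.DataFrame(columns=["anchor_min", "rank", "feature", "value", "contribution"])
    proba = predict(model, X_admission)
    timeline = pd.DataFrame({"anchor_min": anchors_min, "probability": proba})
    att = attribute(model, X_admission)
    k = min(k, len(att.feature_names))
    rows = []
    for i, t in enumerate(anchors_min):
        order = np.argsort(-np.abs(att.contributions[i]))[:k]
        for rank, j in enumerate(order, start=1):
            rows.append({"anchor_min": int(t), "rank": rank,
                         "feature": att.feature_names[j],
                         "value": float(X_admission.iloc[i, j]),
                         "contribution": float(att.contributions[i, j])})
    return timeline, pd.DataFrame(rows)
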