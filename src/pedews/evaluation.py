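"""Imbalanced-class evaluation at a fixed recall set-point.

Deterioration windows are rare (~7% at the default horizon), so ranking
quality is summarised by the area under the precision-recall curve (AUPRC,
average-precision convention — no linear PR interpolation) alongside AUROC.
Deployment behaviour is summarised at a recall set-point of 0.9: the
threshold is the largest score cut achieving recall >= 0.9, where only one
deterioration in ten is missed, and precision ("adjusted precision") and
the harmonic mean of that precision with the achieved recall ("adjusted
F1") are reported there. Repeated retrains are aggregated as mean and SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import UndefinedMetricError

__all__ = [
    "PRMetrics", "AtRecall", "EvalReport",
    "pr_metrics", "metrics_at_recall", "evaluate_scores", "repeated_eval",
    "experiment_grid",
]


@dataclass(frozen=True)
class PRMetrics:
    auprc: float
    auroc: float
    #: PR curve points (threshold, precision, recall), thresholds descending
    curve: pd.DataFrame = field(repr=False, default=None)


@dataclass(frozen=True)
class AtRecall:
    setpoint: float
    threshold: float
    precision: float
    recall: float      # achieved recall at the chosen threshold
    f1: float


@dataclass
class EvalReport:
    """Per-repeat metrics with mean/SD aggregation."""

    setpoint: float
    per_repeat: pd.DataFrame  # columns: repeat, auprc, auroc, precision, f1, recall, threshold
    n_positive: int
    n_negative: int

    @property
    def mean(self) -> pd.Series:
        return self.per_repeat.drop(columns="repeat").mean()

    @property
    def sd(self) -> pd.Series | None:
        if len(self.per_repeat) < 2:
            return None
        return self.per_repeat.drop(columns="repeat").std(ddof=1)


def _check_two_class(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise UndefinedMetricError("metrics undefined on single-class labels")
    return y


def _pr_curve(scores: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """All-thresholds PR points; samples sharing a score enter together."""
    order = np.argsort(-scores, kind="stable")
    s, yy = scores[order], y[order]
    # indices where a threshold block ends (last occurrence of each unique score)
    block_end = np.flatnonzero(np.diff(s, append=-np.inf) != 0)
    tp = np.cumsum(yy)[block_end]
    n_taken = block_end + 1
    precision = tp / n_taken
    recall = tp / y.sum()
    return pd.DataFrame({"threshold": s[block_end], "precision": precision, "recall": recall})


def pr_metrics(scores, labels) -> PRMetrics:
    """AUPRC (average-precision step convention) and AUROC (rank rule, ties half-credit)."""
    scores = np.asarray(scores, float)
    y = _check_two_class(labels)
    return PRMetrics(
        auprc=float(average_precision_score(y, scores)),
        auroc=float(roc_auc_score(y, scores)),
        curve=_pr_curve(scores, y),
    )


def metrics_at_recall(scores, labels, setpoint: float = 0.9) -> AtRecall:
    """Operating point at the largest threshold achieving recall >= setpoint.

    Ties share a threshold (they enter the positive set together). The
    adjusted F1 is the harmonic mean of the precision and the *achieved*
    recall at that threshold. Recall 1.0 is always attainable at the lowest
    score, so the set-point is always reachable.
    """
    scores = np.asarray(scores, float)
    y = _check_two_class(labels)
    curve = _pr_curve(scores, y)
    ok = curve["recall"] >= setpoint
    row = curve[ok].iloc[0]  # thresholds descend, recall ascends -> first hit = largest cut
    p, r = float(row["precision"]), float(row["recall"])
    f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return AtRecall(setpoint=setpoint, threshold=float(row["threshold"]),
                    precision=p, recall=r, f1=f1)


def evaluate_scores(scores, labels, setpoint: float = 0.9) -> dict[str, float]:
    """One repeat's full metric row."""
    pr = pr_metrics(scores, labels)
    at = metrics_at_recall(scores, labels, setpoint)
    return {"auprc": pr.auprc, "auroc": pr.auroc, "precision": at.precision,
            "f1": at.f1, "recall": at.recall, "threshold": at.threshold}


def repeated_eval(
    model_factory,
    X_train, y_train,
    X_test, y_test,
    repeats: int = 10,
    seed: int = 0,
    setpoint: float = 0.9,
    groups_train=None,
) -> EvalReport:
    """Refit with fresh seeds and evaluate on the same holdout each time.

    ``model_factory(seed)`` returns an object with fit/predict_proba-like
    behaviour via :func:`pedews.models.predict`; the holdout windows are
    identical across repeats and across model families by construction.
    """
    from .models import predict  # deferred import to avoid a cycle

    rows = []
    rng = np.random.SeedSequence(seed).generate_state(repeats)
    for r in range(repeats):
        model = model_factory(int(rng[r] % (2**31 - 1)))
        model.fit(X_train, y_train, groups=groups_train)
        scores = predict(model, X_test)
        rows.append({"repeat": r, **evaluate_scores(scores, y_test, setpoint)})
    y = np.asarray(y_test).astype(int)
    return EvalReport(setpoint=setpoint, per_repeat=pd.DataFrame(rows),
                      n_positive=int(y.sum()), n_negative=int((1 - y).sum()))


def experiment_grid(cells: dict[tuple, "EvalReport"]) -> pd.DataFrame:
    """Tidy long table over prepared (family, lookback_h, horizon_h, ablation) cells.

    ``cells`` maps (family, lookback_h, horizon_h, ablation) -> EvalReport;
    the output has one row per cell x repeat x metric.
    """
    rows = []
    for (family, lookback_h, horizon_h, ablation), report in cells.items():
        for _, rep in report.per_repeat.iterrows():
            for metric in ("auprc", "auroc", "precision", "f1"):
                rows.append({
                    "family": family, "lookback_h": lookback_h,
                    "horizon_h": horizon_h, "ablation": ablation,
                    "repeat": int(rep["repeat"]), "metric": metric,
                    "value": float(rep[metric]),
                })
    return pd.DataFrame(rows)
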