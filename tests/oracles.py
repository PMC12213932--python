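"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: explicit loops over thresholds,
minutes and pairs, no shared code with the package paths under test.
"""

from __future__ import annotations

import numpy as np


def auprc_enumeration(scores, labels) -> float:
    """Average precision by explicit enumeration of every threshold block."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = labels.sum()
    thresholds = sorted(set(scores), reverse=True)
    auprc, prev_recall = 0.0, 0.0
    for th in thresholds:
        taken = scores >= th
        tp = int(labels[taken].sum())
        precision = tp / int(taken.sum())
        recall = tp / n_pos
        auprc += (recall - prev_recall) * precision
        prev_recall = recall
    return auprc


def auroc_pairs(scores, labels) -> float:
    """Probability a random positive outranks a random negative; ties half-credit."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def at_recall_enumeration(scores, labels, setpoint: float):
    """Largest threshold with recall >= setpoint; precision and F1 there."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = labels.sum()
    best = None
    for th in sorted(set(scores), reverse=True):
        taken = scores >= th
        tp = int(labels[taken].sum())
        recall = tp / n_pos
        if recall >= setpoint:
            precision = tp / int(taken.sum())
            f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
            best = (th, precision, recall, f1)
            break
    return best


def ols_normal_equations(values, period_min: int = 1):
    """Slope (units/hour) and R^2 from the normal equations, long way round."""
    y = np.asarray(values, float)
    n = len(y)
    t = np.arange(n) * (period_min / 60.0)
    A = np.column_stack([np.ones(n), t])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    yhat = A @ beta
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot <= 1e-24 * max(1.0, y.mean() ** 2) else 1.0 - ss_res / ss_tot
    return float(beta[1]), max(0.0, min(1.0, r2))


def label_minute_scan(
    anchor, lookback_min, horizon_min, cv, lactate, los_min,
    death_min=None, ecmo_min=None, lactate_threshold=2.0,
):
    """Minute-by-minute scan of all four composite deterioration conditions.

    Walks every horizon minute in order and reports the first firing
    condition (death > ecmo > cv rise > lactate at an equal minute),
    mirroring the outcome definition but sharing no code with it.
    """
    t = int(anchor)
    look_lo = max(t - int(lookback_min), 0)
    cv_base = -np.inf
    lac_base = -np.inf
    for m in range(look_lo, min(t + 1, los_min)):
        if not np.isnan(cv[m]):
            cv_base = max(cv_base, cv[m])
        if not np.isnan(lactate[m]):
            lac_base = max(lac_base, lactate[m])

    events = []  # (minute, priority, name)
    if death_min is not None and t < death_min <= t + horizon_min:
        events.append((float(death_min), 0, "death"))
    if ecmo_min is not None and t < ecmo_min <= t + horizon_min:
        events.append((float(ecmo_min), 1, "ecmo"))
    for m in range(t + 1, min(t + int(horizon_min) + 1, los_min)):
        if not np.isnan(cv[m]) and cv[m] > cv_base:
            events.append((float(m), 2, "cv_rise"))
            break
    for m in range(t + 1, min(t + int(horizon_min) + 1, los_min)):
        if not np.isnan(lactate[m]) and lactate[m] >= lactate_threshold and lactate[m] > lac_base:
            events.append((float(m), 3, "lactate"))
            break
    if not events:
        return 0, "none", None
    when, _, name = min(events)
    return 1, name, when
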