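"""Minute-grid coercion, interpolation, carry-forward, imputation, scaling.

Event streams are asynchronous; all downstream window statistics operate on
an admission-relative one-minute grid (minute 0 = admission). Each gridded
minute carries a provenance code so that "frequency of input" can later be
computed from genuinely observed minutes only, and so imputed values can be
distinguished from measured ones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NotFittedError

__all__ = [
    "MISSING", "OBSERVED", "INTERPOLATED", "CARRIED", "IMPUTED",
    "GriddedSeries", "ImputationPolicy", "to_minute_grid", "interpolate",
    "carry_forward_labs", "impute", "PercentileScaler", "AGE_BIN_EDGES_DAYS",
    "age_bin",
]

# provenance codes
MISSING, OBSERVED, INTERPOLATED, CARRIED, IMPUTED = 0, 1, 2, 3, 4

#: age-band edges (days) for age-stratified median imputation:
#: <1 m, 1-11 m, 1-2 y, 2-5 y, 5-12 y, >=12 y
AGE_BIN_EDGES_DAYS = np.array([0.0, 30.0, 365.0, 730.0, 1825.0, 4380.0, np.inf])


def age_bin(age_days: float) -> int:
    return int(np.searchsorted(AGE_BIN_EDGES_DAYS, age_days, side="right") - 1)


@dataclass
class GriddedSeries:
    """One feature on the admission minute grid.

    ``values`` holds NaN where the minute is missing; ``provenance`` is a
    parallel uint8 array of the codes above. Minute 0 is admission; minutes
    run to discharge (exclusive of post-discharge time).
    """

    feature: str
    values: np.ndarray
    provenance: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.provenance = np.asarray(self.provenance, np.uint8)
        assert self.values.shape == self.provenance.shape

    @property
    def n_minutes(self) -> int:
        return len(self.values)

    def copy(self) -> "GriddedSeries":
        return replace(self, values=self.values.copy(), provenance=self.provenance.copy())


def to_minute_grid(
    minutes: np.ndarray,
    values: np.ndarray,
    n_minutes: int,
    feature: str,
    *,
    log: list[str] | None = None,
) -> GriddedSeries:
    """Coerce (minute, value) observations to the grid.

    Same-minute observations are averaged; observations outside
    [0, n_minutes) are dropped with a log entry. ``minutes`` may be float
    offsets from admission; they are floored to whole minutes.
    """
    minutes = np.floor(np.asarray(minutes, float)).astype(np.int64)
    values = np.asarray(values, float)
    inside = (minutes >= 0) & (minutes < n_minutes)
    if log is not None and (~inside).any():
        log.append(f"{feature}: dropped {int((~inside).sum())} observations outside the admission")
    minutes, values = minutes[inside], values[inside]
    out = np.full(n_minutes, np.nan)
    prov = np.zeros(n_minutes, np.uint8)
    if len(minutes):
        sums = np.bincount(minutes, weights=values, minlength=n_minutes)
        counts = np.bincount(minutes, minlength=n_minutes)
        hit = counts > 0
        out[hit] = sums[hit] / counts[hit]
        prov[hit] = OBSERVED
    return GriddedSeries(feature, out, prov)


def interpolate(series: GriddedSeries, max_gap: int = 90) -> GriddedSeries:
    """Linearly fill gaps of at most ``max_gap`` minutes between observed minutes.

    Longer gaps stay wholly missing (no partial fill) and there is no
    extrapolation before the first or after the last observation. Observed
    minutes are never altered; the operation is idempotent.
    """
    s = series.copy()
    obs = np.flatnonzero(s.provenance != MISSING)
    if len(obs) < 2:
        return s
    gaps = np.diff(obs)
    for i in np.flatnonzero((gaps > 1) & (gaps <= max_gap)):
        lo, hi = obs[i], obs[i + 1]
        interior = np.arange(lo + 1, hi)
        s.values[interior] = np.interp(interior, [lo, hi], [s.values[lo], s.values[hi]])
        s.provenance[interior] = INTERPOLATED
    return s


def carry_forward_labs(series: GriddedSeries, max_carry_min: int = 4 * 24 * 60) -> GriddedSeries:
    """Step-function carry of the last value for at most ``max_carry_min`` minutes.

    Intended for sparse laboratory results: no interpolation between
    results, the earlier value holds until the next result or until the
    carry limit expires (after which the minutes revert to missing, for
    imputation).
    """
    s = series.copy()
    obs = np.flatnonzero(s.provenance == OBSERVED)
    n = s.n_minutes
    for j, start in enumerate(obs):
        nxt = obs[j + 1] if j + 1 < len(obs) else n
        end = min(nxt, start + max_carry_min + 1, n)
        if end > start + 1:
            s.values[start + 1:end] = s.values[start]
            s.provenance[start + 1:end] = CARRIED
    return s


@dataclass
class ImputationPolicy:
    """feature -> imputation strategy.

    Strategies: ``age_stratified_median`` (cohort median within the
    patient's age band), ``global_median`` (cohort median), and
    ``assume_absent`` (a fixed value encoding informative missingness, e.g.
    ventilation level 0 = no respiratory support).
    """

    strategies: dict[str, tuple[str, float | None]]

    _VALID = {"age_stratified_median", "global_median", "assume_absent"}

    def __post_init__(self) -> None:
        for feat, (strategy, _) in self.strategies.items():
            if strategy not in self._VALID:
                raise ConfigurationError(f"unknown imputation strategy {strategy!r} for {feat!r}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ImputationPolicy":
        df = pd.read_csv(path)
        strategies = {}
        for row in df.itertuples(index=False):
            param = None if pd.isna(row.parameter) else float(row.parameter)
            strategies[row.feature] = (row.strategy, param)
        return cls(strategies)

    def strategy_for(self, feature: str) -> tuple[str, float | None]:
        if feature not in self.strategies:
            raise ConfigurationError(f"no imputation strategy configured for feature {feature!r}")
        return self.strategies[feature]


def impute(
    series: GriddedSeries,
    policy: ImputationPolicy,
    age_days: float,
    cohort_medians: dict[str, float | np.ndarray],
) -> GriddedSeries:
    """Fill every remaining missing minute per the policy.

    ``cohort_medians`` maps feature -> scalar (global strategy) or an array
    indexed by age bin (age-stratified strategy); medians must have been
    computed on the training split only to avoid leakage.
    """
    strategy, param = policy.strategy_for(series.feature)
    s = series.copy()
    hole = s.provenance == MISSING
    if not hole.any():
        return s
    if strategy == "assume_absent":
        fill = float(param)
    elif strategy == "global_median":
        fill = float(cohort_medians[series.feature])
    else:
        fill = float(np.asarray(cohort_medians[series.feature])[age_bin(age_days)])
    s.values[hole] = fill
    s.provenance[hole] = IMPUTED
    return s


class PercentileScaler:
    """Rank-to-[0,1] scaling fitted on training values only.

    A value maps to its mid-rank empirical CDF position
    ``(#less + 0.5 * #equal) / n``; values beyond the training range clip to
    0/1. A single monotone map, robust to outliers.
    """

    def __init__(self) -> None:
        self._sorted: dict[str, np.ndarray] | None = None

    def fit(self, columns: dict[str, np.ndarray] | pd.DataFrame) -> "PercentileScaler":
        if isinstance(columns, pd.DataFrame):
            columns = {c: columns[c].to_numpy(float) for c in columns.columns}
        self._sorted = {}
        for name, vals in columns.items():
            vals = np.asarray(vals, float)
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                raise ConfigurationError(f"no finite training values to fit scaler for {name!r}")
            self._sorted[name] = np.sort(vals)
        return self

    def transform_column(self, name: str, values: np.ndarray | float) -> np.ndarray | float:
        if self._sorted is None:
            raise NotFittedError("PercentileScaler.transform called before fit")
        if name not in self._sorted:
            raise ConfigurationError(f"scaler was not fitted for column {name!r}")
        ref = self._sorted[name]
        scalar = np.isscalar(values) or np.ndim(values) == 0
        v = np.atleast_1d(np.asarray(values, float))
        less = np.searchsorted(ref, v, side="left")
        less_eq = np.searchsorted(ref, v, side="right")
        out = (less + 0.5 * (less_eq - less)) / len(ref)
        return float(out[0]) if scalar else out

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {c: self.transform_column(c, df[c].to_numpy(float)) for c in df.columns},
            index=df.index,
        )
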