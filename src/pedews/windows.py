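"""Lookback windows and per-window summary statistics.

Each prediction is anchored at a time t and summarises the preceding
lookback interval [t - L, t) on the minute grid: mean, variability (sample
SD), linear trend (slope in units/hour), strength of trend (OLS R^2),
frequency of input (observed minutes per hour, from provenance so that
interpolation does not inflate it), and the latest value. Anchors start at
admission + L and advance by a fixed stride; admissions shorter than L
yield no samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import OBSERVED, GriddedSeries

__all__ = [
    "WindowSpec", "WindowSummary", "window_anchors", "summarise",
    "summarise_windows", "resample", "ablate", "SERIES_STATS",
]

#: statistics computed for every time-series feature, in column order
SERIES_STATS = ("mean", "sd", "slope", "r2", "freq", "latest")


@dataclass(frozen=True)
class WindowSpec:
    """Lookback/horizon geometry for window cutting.

    lookback_h in {3, 6, 12}; horizon_h in {3, 6, 9, 12, 18, 24};
    stride_min >= 1; resample_min in {1, 15, 60} thins the grid before
    summarising (sampling-frequency ablation).
    """

    lookback_h: float = 6.0
    horizon_h: float = 12.0
    stride_min: int = 60
    resample_min: int = 1

    def __post_init__(self) -> None:
        if self.lookback_h <= 0 or self.horizon_h <= 0:
            raise ValueError("lookback and horizon must be positive")
        if self.stride_min < 1 or self.resample_min < 1:
            raise ValueError("stride and resample period must be >= 1 minute")

    @property
    def lookback_min(self) -> int:
        return int(round(self.lookback_h * 60))

    @property
    def horizon_min(self) -> int:
        return int(round(self.horizon_h * 60))


@dataclass
class WindowSummary:
    mean: float
    sd: float
    slope: float
    r2: float
    freq: float
    latest: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.mean, self.sd, self.slope, self.r2, self.freq, self.latest)


def window_anchors(los_min: int, spec: WindowSpec) -> np.ndarray:
    """Anchor minutes: admission + L, then every stride until discharge.

    Count is max(0, floor((LOS - L)/stride) + 1); an admission shorter than
    the lookback yields no anchors.
    """
    L = spec.lookback_min
    if los_min < L:
        return np.empty(0, np.int64)
    return np.arange(L, los_min + 1, spec.stride_min, dtype=np.int64)


def summarise(
    values: np.ndarray,
    observed_mask: np.ndarray,
    lookback_h: float,
    period_min: int = 1,
) -> WindowSummary:
    """Summary statistics for one fully-imputed window.

    ``values`` are the window's grid values (oldest first, grid step
    ``period_min`` minutes); ``observed_mask`` flags genuinely observed
    minutes. Slope and R^2 come from OLS of value on time-in-hours.
    Degenerate conventions: constant series -> sd 0, slope 0, R^2 0; a
    single point -> slope 0, R^2 0.
    """
    x = np.asarray(values, float)
    n = len(x)
    if n == 0:
        raise AssertionError("empty window after imputation")
    mu = float(x.mean())
    freq = float(np.asarray(observed_mask, bool).sum() / lookback_h)
    latest = float(x[-1])
    if n == 1:
        return WindowSummary(mu, 0.0, 0.0, 0.0, freq, latest)
    t = np.arange(n) * (period_min / 60.0)
    tc = t - t.mean()
    xc = x - mu
    sxx = float(xc @ xc)
    sd = float(np.sqrt(sxx / (n - 1)))
    stt = float(tc @ tc)
    if sxx <= 1e-24 * max(1.0, mu * mu) or stt == 0.0:
        return WindowSummary(mu, sd, 0.0, 0.0, freq, latest)
    slope = float((tc @ xc) / stt)
    r2 = float(min(max(slope * slope * stt / sxx, 0.0), 1.0))
    return WindowSummary(mu, sd, slope, r2, freq, latest)


def summarise_windows(
    series: GriddedSeries, anchors: np.ndarray, spec: WindowSpec
) -> np.ndarray:
    """Vectorised summaries over many anchors: (n_anchors, 6) array in SERIES_STATS order."""
    L, p = spec.lookback_min, spec.resample_min
    anchors = np.asarray(anchors, np.int64)
    if len(anchors) == 0:
        return np.empty((0, len(SERIES_STATS)))
    offsets = np.arange(0, L, p, dtype=np.int64)
    idx = anchors[:, None] - L + offsets[None, :]
    X = series.values[idx]
    obs = (series.provenance[idx] == OBSERVED).sum(axis=1)
    m = X.shape[1]
    mu = X.mean(axis=1)
    freq = obs / spec.lookback_h
    latest = series.values[anchors - 1]
    if m == 1:
        zero = np.zeros_like(mu)
        return np.column_stack([mu, zero, zero, zero, freq, latest])
    Xc = X - mu[:, None]
    sxx = np.einsum("ij,ij->i", Xc, Xc)
    sd = np.sqrt(sxx / (m - 1))
    t = offsets * (1.0 / 60.0)
    tc = t - t.mean()
    stt = float(tc @ tc)
    slope = (Xc @ tc) / stt
    scale = np.maximum(1.0, mu * mu)
    flat = sxx <= 1e-24 * scale
    slope[flat] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(flat, 0.0, slope * slope * stt / np.where(flat, 1.0, sxx))
    r2 = np.clip(r2, 0.0, 1.0)
    return np.column_stack([mu, sd, slope, r2, freq, latest])


def resample(series: GriddedSeries, period_min: int) -> GriddedSeries:
    """Thin a gridded series to every ``period_min``-th minute from its start."""
    return GriddedSeries(
        series.feature,
        series.values[::period_min].copy(),
        series.provenance[::period_min].copy(),
    )


@dataclass
class FeatureRegistry:
    """Fixed ordering of feature-matrix columns with their provenance.

    ``columns`` rows: (column, feature, stat) where stat is one of
    SERIES_STATS for time-series features, "latest" for labs, or "static".
    """

    columns: pd.DataFrame = field(repr=False)

    @property
    def names(self) -> list[str]:
        return self.columns["column"].tolist()

    def select(self, mask: pd.Series) -> list[str]:
        return self.columns.loc[mask, "column"].tolist()


def ablate(
    X: pd.DataFrame,
    registry: FeatureRegistry,
    mode: str,
    k: int | None = None,
    ranking: list[str] | None = None,
) -> tuple[pd.DataFrame, FeatureRegistry]:
    """Reduced-input experiment variants.

    latest_only keeps each feature's last value (plus static features);
    no_frequency drops frequency-of-input columns; no_trend drops slope and
    R^2 columns; topk keeps the k highest-ranked columns of a supplied
    importance ranking.
    """
    cols = registry.columns
    if mode == "latest_only":
        keep = cols["stat"].isin(["latest", "static"])
    elif mode == "no_frequency":
        keep = cols["stat"] != "freq"
    elif mode == "no_trend":
        keep = ~cols["stat"].isin(["slope", "r2"])
    elif mode == "topk":
        if ranking is None or k is None:
            raise ValueError("topk ablation needs a ranking and k")
        if k >= len(cols):
            warnings.warn(f"topk k={k} >= {len(cols)} available columns; keeping all")
            keep = pd.Series(True, index=cols.index)
        else:
            chosen = set(ranking[:k])
            keep = cols["column"].isin(chosen)
    else:
        raise ValueError(f"unknown ablation mode {mode!r}")
    kept = registry.select(keep)
    return X[kept], FeatureRegistry(cols[keep].reset_index(drop=True))
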