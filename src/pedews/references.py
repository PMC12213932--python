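"""Age/sex-stratified reference ranges and normalisation transforms.

Paediatric vital signs have strongly age-dependent normal ranges: a heart
rate of 140 bpm is unremarkable in a neonate and alarming in a teenager.
This module houses the centile tables used to map raw vitals onto an
age-invariant unit-interval score, the LMS (lambda-mu-sigma) growth
references used for weight/height z-scores, and the age-banded mean
arterial pressure (MAP) lower limits used by the cardiovascular organ
dysfunction sub-score.

The numeric tables shipped under ``pedews/data`` are editable package
defaults with a documented schema, not reproductions of any published
centile charts; any table with the same schema can be substituted via
``reference_dir``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidReferenceError

__all__ = [
    "CentileTable",
    "LMSTable",
    "PSofaMapThresholds",
    "centile_normalise",
    "dbp_lower_limit",
    "map_from_sbp_dbp",
    "growth_zscore",
    "default_reference_dir",
]

#: centile grid column -> cumulative probability
_CENTILE_COLS = {"c1": 0.01, "c10": 0.10, "c25": 0.25, "c50": 0.50,
                 "c75": 0.75, "c90": 0.90, "c99": 0.99}


def default_reference_dir() -> Path:
    """Directory of the packaged default reference CSVs."""
    return Path(resources.files("pedews").joinpath("data"))


@dataclass
class CentileTable:
    """Centile grid per (variable, age band, sex).

    Age bands are half-open ``[age_low_days, age_high_days)`` and must
    partition the covered age range without overlap. Centile values must be
    strictly increasing along the grid within each row.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"variable", "age_low_days", "age_high_days", "sex", *_CENTILE_COLS}
        missing = required - set(self.df.columns)
        if missing:
            raise ConfigurationError(f"centile table missing columns: {sorted(missing)}")
        vals = self.df[list(_CENTILE_COLS)].to_numpy(float)
        if not (np.diff(vals, axis=1) > 0).all():
            raise ConfigurationError("centile grid values must be strictly increasing")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CentileTable":
        return cls(pd.read_csv(path))

    def row(self, variable: str, age_days: float, sex: str = "any") -> pd.Series:
        df = self.df
        m = (df["variable"] == variable) & (df["age_low_days"] <= age_days) & (age_days < df["age_high_days"])
        sub = df[m]
        if len(sub) > 1:  # prefer the sex-specific row when one exists
            sexed = sub[sub["sex"] == sex]
            sub = sexed if len(sexed) else sub[sub["sex"] == "any"]
        if len(sub) == 0:
            raise ConfigurationError(
                f"no centile row for variable={variable!r}, age={age_days:.0f} d, sex={sex!r}"
            )
        return sub.iloc[0]

    def grid(self, variable: str, age_days: float, sex: str = "any") -> tuple[np.ndarray, np.ndarray]:
        """Return (probabilities, values) for the covering age band."""
        row = self.row(variable, age_days, sex)
        probs = np.array(list(_CENTILE_COLS.values()))
        values = row[list(_CENTILE_COLS)].to_numpy(float)
        return probs, values


def centile_normalise(
    variable: str,
    value: float | np.ndarray,
    age_days: float,
    sex: str,
    table: CentileTable,
) -> float | np.ndarray:
    """Map a raw value to its interpolated centile position in [0, 1].

    Linear interpolation between tabulated (value, probability) pairs;
    values beyond the outermost tabulated centiles clip to the outermost
    grid probabilities. Monotone non-decreasing in ``value`` at fixed
    age/sex.
    """
    probs, grid_values = table.grid(variable, age_days, sex)
    out = np.interp(np.asarray(value, float), grid_values, probs)
    if np.isscalar(value) or np.ndim(value) == 0:
        return float(out)
    return out


def map_from_sbp_dbp(sbp: float, dbp: float) -> float:
    """Forward mean arterial pressure relationship MAP = (SBP - DBP)/3 + DBP."""
    return (sbp - dbp) / 3.0 + dbp


def dbp_lower_limit(map_ll: float, sbp_ll: float) -> float:
    """Back-calculate the diastolic lower limit from MAP and SBP lower limits.

    Inverts MAP = (SBP - DBP)/3 + DBP, giving DBP = (3*MAP - SBP)/2.
    Re-applying :func:`map_from_sbp_dbp` recovers ``map_ll`` exactly.
    """
    if not (sbp_ll >= map_ll > 0):
        raise InvalidReferenceError(f"need sbp_ll >= map_ll > 0, got sbp={sbp_ll}, map={map_ll}")
    dbp = (3.0 * map_ll - sbp_ll) / 2.0
    if dbp <= 0:
        raise InvalidReferenceError(f"derived DBP lower limit {dbp:.1f} mmHg is non-positive")
    return dbp


@dataclass
class LMSTable:
    """LMS (skewness L, median M, coefficient of variation S) growth reference."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"measure", "sex", "age_days", "L", "M", "S"}
        missing = required - set(self.df.columns)
        if missing:
            raise ConfigurationError(f"LMS table missing columns: {sorted(missing)}")
        if (self.df["M"] <= 0).any() or (self.df["S"] <= 0).any():
            raise ConfigurationError("LMS M and S must be positive")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LMSTable":
        return cls(pd.read_csv(path))

    def lms(self, measure: str, age_days: float, sex: str = "any") -> tuple[float, float, float]:
        """Age-interpolated (L, M, S) for the measure, nearest-neighbour at the edges."""
        sub = self.df[self.df["measure"] == measure]
        if len(sub) == 0:
            raise ConfigurationError(f"no LMS rows for measure {measure!r}")
        sexed = sub[sub["sex"] == sex]
        sub = (sexed if len(sexed) else sub[sub["sex"] == "any"]).sort_values("age_days")
        ages = sub["age_days"].to_numpy(float)
        L = float(np.interp(age_days, ages, sub["L"].to_numpy(float)))
        M = float(np.interp(age_days, ages, sub["M"].to_numpy(float)))
        S = float(np.interp(age_days, ages, sub["S"].to_numpy(float)))
        return L, M, S


def growth_zscore(
    measure: str, value: float, age_days: float, sex: str, table: LMSTable
) -> float:
    """LMS z-score: ((value/M)**L - 1)/(L*S), or ln(value/M)/S as L -> 0."""
    if not value > 0:
        raise ValueError(f"{measure} must be positive, got {value}")
    L, M, S = table.lms(measure, age_days, sex)
    if abs(L) < 1e-7:
        return float(np.log(value / M) / S)
    return float(((value / M) ** L - 1.0) / (L * S))


@dataclass
class PSofaMapThresholds:
    """Age-banded MAP lower limits for the cardiovascular sub-score.

    Bands are half-open in months; thresholds are non-decreasing with age.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"age_low_months", "age_high_months", "map_ll_mmhg"}
        missing = required - set(self.df.columns)
        if missing:
            raise ConfigurationError(f"MAP threshold table missing columns: {sorted(missing)}")
        ordered = self.df.sort_values("age_low_months")["map_ll_mmhg"].to_numpy(float)
        if (ordered <= 0).any() or (np.diff(ordered) < 0).any():
            raise ConfigurationError("MAP thresholds must be positive and non-decreasing with age")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PSofaMapThresholds":
        return cls(pd.read_csv(path))

    def lower_limit(self, age_months: float) -> float:
        df = self.df
        m = (df["age_low_months"] <= age_months) & (age_months < df["age_high_months"])
        sub = df[m]
        if len(sub) == 0:
            raise ConfigurationError(f"no MAP threshold band covers age {age_months:.1f} months")
        return float(sub.iloc[0]["map_ll_mmhg"])


@dataclass
class ReferenceSet:
    """Bundle of all reference tables loaded from one directory."""

    centiles: CentileTable
    lms: LMSTable
    psofa_map: PSofaMapThresholds
    psofa_bands: pd.DataFrame = field(repr=False, default=None)

    @classmethod
    def load(cls, reference_dir: str | Path | None = None) -> "ReferenceSet":
        d = Path(reference_dir) if reference_dir is not None else default_reference_dir()
        for name in ("centiles.csv", "lms.csv", "psofa_map.csv", "psofa_bands.csv"):
            if not (d / name).exists():
                raise ConfigurationError(f"reference file {name} not found in {d}")
        return cls(
            centiles=CentileTable.from_csv(d / "centiles.csv"),
            lms=LMSTable.from_csv(d / "lms.csv"),
            psofa_map=PSofaMapThresholds.from_csv(d / "psofa_map.csv"),
            psofa_bands=pd.read_csv(d / "psofa_bands.csv"),
        )
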