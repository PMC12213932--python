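"""Consolidation of raw EHR variables into canonical engineered features.

Monitors, devices and laboratory feeds report overlapping quantities under
different names (e.g. arterial and cuff systolic pressure). A variable map
merges these aliases onto canonical features with unit conversion and a
device priority, ventilatory support is collapsed to a four-level ordinal
score, and vasoactive infusions are summarised by the vasoactive inotrope
score (VIS).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "VariableMap",
    "VasoactiveDoses",
    "VentilationState",
    "ventilation_level",
    "vis_score",
    "consolidate",
    "weight_normalise",
    "VIS_COEFFICIENTS",
]

#: VIS = dop + dob + 10*milrinone + 100*epi + 100*norepi + 10000*vasopressin,
#: all dose rates in ug/kg/min (vasopressin in U/kg/min). Config default per
#: the standard VIS definition.
VIS_COEFFICIENTS: dict[str, float] = {
    "dopamine": 1.0,
    "dobutamine": 1.0,
    "milrinone": 10.0,
    "epinephrine": 100.0,
    "norepinephrine": 100.0,
    "vasopressin": 10000.0,
}


@dataclass(frozen=True)
class VasoactiveDoses:
    """Infusion dose rates, already weight-normalised (ug/kg/min; vasopressin U/kg/min)."""

    dopamine: float = 0.0
    dobutamine: float = 0.0
    milrinone: float = 0.0
    epinephrine: float = 0.0
    norepinephrine: float = 0.0
    vasopressin: float = 0.0

    def __post_init__(self) -> None:
        for name in VIS_COEFFICIENTS:
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name} dose")


def vis_score(doses: VasoactiveDoses) -> float:
    """Vasoactive inotrope score: weighted sum of per-kg dose rates.

    Linear and additive in the doses; zero iff all doses are zero.
    """
    return float(sum(coef * getattr(doses, name) for name, coef in VIS_COEFFICIENTS.items()))


@dataclass(frozen=True)
class VentilationState:
    """Resolved respiratory-support indicators for one minute.

    ``fio2`` is the fraction of inspired oxygen when a device reports one.
    """

    room_air: bool = False
    supplemental_o2: bool = False
    positive_pressure: bool = False
    invasive: bool = False
    fio2: float | None = None


def ventilation_level(state: VentilationState) -> int:
    """Ordinal ventilatory-support level.

    0 = no support (breathing room air unassisted), 1 = supplemental oxygen
    only (e.g. facemask oxygen), 2 = positive-pressure airway support (e.g.
    high-flow nasal oxygen or non-invasive ventilation), 3 = invasive
    mechanical ventilation (endotracheal or tracheostomy tube). When several
    indicators fire, the highest level of support wins.
    """
    if state.invasive:
        return 3
    if state.positive_pressure:
        return 2
    if state.supplemental_o2:
        return 1
    return 0


@dataclass
class VariableMap:
    """alias -> (canonical feature, unit conversion factor, priority rank).

    Priority 1 is the most trusted source for a canonical feature (e.g.
    arterial over cuff blood pressure); factors multiply raw values into the
    canonical unit.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"alias", "canonical", "factor", "priority", "unit"}
        missing = required - set(self.df.columns)
        if missing:
            raise ConfigurationError(f"variable map missing columns: {sorted(missing)}")
        if self.df["alias"].duplicated().any():
            dups = self.df.loc[self.df["alias"].duplicated(), "alias"].tolist()
            raise ConfigurationError(f"aliases mapped more than once: {dups}")
        if (self.df["factor"] <= 0).any():
            raise ConfigurationError("conversion factors must be positive")

    @classmethod
    def from_csv(cls, path: str | Path) -> "VariableMap":
        return cls(pd.read_csv(path))

    @property
    def aliases(self) -> set[str]:
        return set(self.df["alias"])


def consolidate(
    events: pd.DataFrame, vmap: VariableMap, *, log: list[str] | None = None
) -> pd.DataFrame:
    """Merge aliased variables onto canonical features.

    ``events`` is a long table with at least columns
    ``(patient_id, admission_id, timestamp, variable, value)``; an optional
    ``unit`` column is checked against the map. Unmapped variables are
    dropped (and noted in ``log``). Within the same canonical feature and
    minute, the highest-priority (lowest rank) source wins; remaining
    same-priority ties are averaged downstream by the minute-grid rule.
    """
    df = events.merge(vmap.df, left_on="variable", right_on="alias", how="left")
    unmapped = df["canonical"].isna()
    if unmapped.any():
        dropped = sorted(df.loc[unmapped, "variable"].unique())
        if log is not None:
            log.append(f"consolidate: dropped {int(unmapped.sum())} rows from unmapped variables {dropped}")
        df = df[~unmapped]
    if "unit" in events.columns:
        bad = df["unit_x"].notna() & (df["unit_x"] != df["unit_y"])
        if bad.any():
            pairs = df.loc[bad, ["variable", "unit_x", "unit_y"]].drop_duplicates()
            raise ConfigurationError(
                "unit mismatch without conversion: "
                + "; ".join(f"{v} reported {a!r}, map expects {b!r}" for v, a, b in pairs.itertuples(index=False))
            )
    out = df.assign(value=df["value"] * df["factor"], variable=df["canonical"])
    # priority rule: within one canonical feature-minute keep only the best rank
    minute = out["timestamp"].values.astype("datetime64[m]")
    out = out.assign(_minute=minute)
    best = out.groupby(["admission_id", "variable", "_minute"])["priority"].transform("min")
    out = out[out["priority"] == best]
    keep = [c for c in ("patient_id", "admission_id", "timestamp", "variable", "value") if c in out.columns]
    out = out[keep + ["unit_y"]].rename(columns={"unit_y": "unit"})
    return out.reset_index(drop=True)


def weight_normalise(value: float | np.ndarray, weight_kg: float) -> float | np.ndarray:
    """Divide a dose/flow by body weight (kg)."""
    if not weight_kg > 0:
        raise ValueError(f"weight must be positive, got {weight_kg}")
    return value / weight_kg
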