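"""Cardiovascular organ-dysfunction scoring and composite deterioration labels.

The primary outcome is cardiovascular deterioration within a horizon H after
the prediction anchor t, defined as any of:

* a rise in the cardiovascular sub-score of the paediatric organ-dysfunction
  (pSOFA-style) score relative to its lookback-window maximum,
* plasma lactate >= 2 mmol/l and increasing relative to the previous
  time-window maximum,
* a new requirement for extra-corporeal membrane oxygenation (ECMO), or
* death,

evaluated over (t, t + H], truncated at discharge. The cardiovascular
sub-score grades hypotension (age-banded MAP lower limits) and vasoactive
support intensity, with milrinone treated as equivalent to dobutamine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .features import VasoactiveDoses
from .references import PSofaMapThresholds

__all__ = [
    "CV_DOSE_BANDS", "DeteriorationLabel", "PSofaVector",
    "cv_subscore", "cv_subscore_series", "label_window", "label_admission",
    "component_score", "psofa_total", "secondary_labels",
]

#: configurable dose-band edges (ug/kg/min) for the cardiovascular sub-score
CV_DOSE_BANDS = {"dopamine_low": 5.0, "dopamine_high": 15.0, "epi_norepi": 0.1}

#: deterministic trigger precedence when several conditions fire at the same minute
_TRIGGER_ORDER = {"death": 0, "ecmo": 1, "cv_rise": 2, "lactate": 3}


def cv_subscore(
    map_mmhg: float,
    age_months: float,
    doses: VasoactiveDoses,
    thresholds: PSofaMapThresholds,
    bands: dict[str, float] = CV_DOSE_BANDS,
) -> float:
    """Cardiovascular sub-score in {0..4}; NaN when MAP is missing and no vasoactives run.

    0: MAP at or above the age threshold, no vasoactives. 1: hypotension
    (MAP below threshold) without vasoactives. 2: low-dose dopamine
    (<= dopamine_low), any dobutamine, or — the milrinone modification —
    any milrinone. 3: dopamine above dopamine_low, or
    epinephrine/norepinephrine at or below epi_norepi. 4: dopamine above
    dopamine_high, epinephrine/norepinephrine above epi_norepi, or any
    vasopressin. The highest applicable band wins.
    """
    score = _dose_band(doses.dopamine, doses.dobutamine, doses.milrinone,
                       doses.epinephrine, doses.norepinephrine, doses.vasopressin, bands)
    if score > 0:
        return float(score)
    if map_mmhg is None or (isinstance(map_mmhg, float) and np.isnan(map_mmhg)):
        return float("nan")
    return 0.0 if map_mmhg >= thresholds.lower_limit(age_months) else 1.0


def _dose_band(dop, dob, mil, epi, nor, vas, bands) -> int:
    if dop > bands["dopamine_high"] or epi > bands["epi_norepi"] or nor > bands["epi_norepi"] or vas > 0:
        return 4
    if dop > bands["dopamine_low"] or 0 < epi or 0 < nor:
        return 3
    if dop > 0 or dob > 0 or mil > 0:
        return 2
    return 0


def cv_subscore_series(
    map_values: np.ndarray,
    dose_series: dict[str, np.ndarray],
    age_months: float,
    thresholds: PSofaMapThresholds,
    bands: dict[str, float] = CV_DOSE_BANDS,
) -> np.ndarray:
    """Vectorised minute-wise cardiovascular sub-score.

    ``dose_series`` maps drug name -> per-minute dose array (missing drugs
    are treated as zero throughout).
    """
    n = len(map_values)
    zero = np.zeros(n)
    get = lambda k: np.nan_to_num(np.asarray(dose_series.get(k, zero), float))
    dop, dob, mil = get("dopamine"), get("dobutamine"), get("milrinone")
    epi, nor, vas = get("epinephrine"), get("norepinephrine"), get("vasopressin")
    score = np.zeros(n)
    score[(dop > 0) | (dob > 0) | (mil > 0)] = 2
    score[(dop > bands["dopamine_low"]) | ((epi > 0) & (epi <= bands["epi_norepi"]))
          | ((nor > 0) & (nor <= bands["epi_norepi"]))] = 3
    score[(dop > bands["dopamine_high"]) | (epi > bands["epi_norepi"])
          | (nor > bands["epi_norepi"]) | (vas > 0)] = 4
    no_drug = score == 0
    mapv = np.asarray(map_values, float)
    ll = thresholds.lower_limit(age_months)
    score[no_drug & (mapv < ll)] = 1.0
    score[no_drug & np.isnan(mapv)] = np.nan
    return score


@dataclass(frozen=True)
class DeteriorationLabel:
    anchor_min: int
    horizon_h: float
    label: int
    trigger: str  # cv_rise | lactate | ecmo | death | none
    trigger_min: float | None


def _window_max(arr: np.ndarray, lo: int, hi: int) -> float:
    """nanmax over arr[lo:hi], -inf when empty or all-NaN (no baseline information)."""
    seg = arr[max(lo, 0):max(hi, 0)]
    if len(seg) == 0 or np.all(np.isnan(seg)):
        return -np.inf
    return float(np.nanmax(seg))


def label_window(
    anchor_min: int,
    lookback_min: int,
    horizon_min: int,
    cv: np.ndarray,
    lactate: np.ndarray,
    los_min: int,
    death_min: float | None = None,
    ecmo_min: float | None = None,
    lactate_threshold: float = 2.0,
    baseline: str = "lookback_max",
) -> DeteriorationLabel:
    """Composite deterioration label for one anchored window.

    ``cv`` and ``lactate`` are minute-gridded admission series (length
    ``los_min``). The horizon (t, t + H] is truncated at discharge for the
    gridded conditions; death and ECMO times come from the admission record.
    The cv-rise baseline is the lookback-window maximum by default
    (``baseline="lookback_max"``), symmetric with the lactate rule; set
    ``baseline="at_anchor"`` to compare against the value at t instead.
    The trigger reported is the first condition to fire in time (precedence
    death > ecmo > cv_rise > lactate at an equal minute).
    """
    t, L, H = int(anchor_min), int(lookback_min), int(horizon_min)
    lo, hi = max(t - L, 0), min(t + H + 1, los_min)  # horizon (t, t+H] inclusive
    firing: list[tuple[float, int, str]] = []

    if baseline == "lookback_max":
        cv_base = _window_max(cv, lo, t + 1)  # [t-L, t] inclusive of the anchor minute
    elif baseline == "at_anchor":
        cv_base = cv[min(t, los_min - 1)] if los_min else -np.inf
        cv_base = -np.inf if np.isnan(cv_base) else float(cv_base)
    else:
        raise ConfigurationError(f"unknown cv-rise baseline mode {baseline!r}")
    horizon = slice(t + 1, hi)
    with np.errstate(invalid="ignore"):
        cv_hits = np.flatnonzero(cv[horizon] > cv_base)
    if len(cv_hits):
        firing.append((t + 1 + cv_hits[0], _TRIGGER_ORDER["cv_rise"], "cv_rise"))

    lac_base = _window_max(lactate, lo, t + 1)
    with np.errstate(invalid="ignore"):
        lac_hits = np.flatnonzero((lactate[horizon] >= lactate_threshold) & (lactate[horizon] > lac_base))
    if len(lac_hits):
        firing.append((t + 1 + lac_hits[0], _TRIGGER_ORDER["lactate"], "lactate"))

    if ecmo_min is not None and t < ecmo_min <= t + H:
        firing.append((float(ecmo_min), _TRIGGER_ORDER["ecmo"], "ecmo"))
    if death_min is not None and t < death_min <= t + H:
        firing.append((float(death_min), _TRIGGER_ORDER["death"], "death"))

    if not firing:
        return DeteriorationLabel(t, H / 60.0, 0, "none", None)
    when, _, trig = min(firing)
    return DeteriorationLabel(t, H / 60.0, 1, trig, float(when))


def label_admission(
    anchors: np.ndarray,
    lookback_min: int,
    horizon_min: int,
    cv: np.ndarray,
    lactate: np.ndarray,
    los_min: int,
    death_min: float | None = None,
    ecmo_min: float | None = None,
    lactate_threshold: float = 2.0,
    baseline: str = "lookback_max",
) -> pd.DataFrame:
    """Label every anchor of one admission; returns a tidy labels table."""
    rows = [
        label_window(t, lookback_min, horizon_min, cv, lactate, los_min,
                     death_min, ecmo_min, lactate_threshold, baseline)
        for t in np.asarray(anchors, np.int64)
    ]
    return pd.DataFrame(
        {
            "anchor_min": [r.anchor_min for r in rows],
            "horizon_h": [r.horizon_h for r in rows],
            "label": [r.label for r in rows],
            "trigger": [r.trigger for r in rows],
            "trigger_min": [r.trigger_min for r in rows],
        }
    )


@dataclass(frozen=True)
class PSofaVector:
    """Six organ-system sub-scores (0-4 each); total is their sum (0-24)."""

    respiratory: int
    coagulation: int
    hepatic: int
    cardiovascular: int
    neurological: int
    renal: int

    @property
    def total(self) -> int:
        return (self.respiratory + self.coagulation + self.hepatic
                + self.cardiovascular + self.neurological + self.renal)

    def as_dict(self) -> dict[str, int]:
        return {
            "respiratory": self.respiratory, "coagulation": self.coagulation,
            "hepatic": self.hepatic, "cardiovascular": self.cardiovascular,
            "neurological": self.neurological, "renal": self.renal,
        }


def component_score(
    component: str, value: float, age_months: float, bands: pd.DataFrame
) -> int:
    """Band-table lookup for one non-cardiovascular sub-score; missing input -> 0."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return 0
    sub = bands[(bands["component"] == component)
                & (bands["age_low_months"] <= age_months)
                & (age_months < bands["age_high_months"])]
    if len(sub) == 0:
        raise ConfigurationError(f"no {component!r} band covers age {age_months:.1f} months")
    score = 0
    for row in sub.itertuples(index=False):
        hit = (value < row.threshold if row.direction == "lt"
               else value <= row.threshold if row.direction == "le"
               else value >= row.threshold)
        if hit:
            score = max(score, int(row.score))
    return score


def psofa_total(
    inputs: dict[str, float],
    age_months: float,
    bands: pd.DataFrame,
    map_thresholds: PSofaMapThresholds,
    doses: VasoactiveDoses | None = None,
    vent_level: int = 0,
) -> PSofaVector:
    """Full six-component organ-dysfunction vector for one minute.

    ``inputs`` may contain sf_ratio (SpO2:FiO2), platelets (10^9/l),
    bilirubin (umol/l), gcs, creatinine (umol/l) and map (mmHg); a missing
    input scores 0 for its system. Respiratory scores above 2 require
    positive-pressure or invasive support.
    """
    doses = doses or VasoactiveDoses()
    resp = component_score("respiratory", inputs.get("sf_ratio", np.nan), age_months, bands)
    if vent_level < 2:
        resp = min(resp, 2)
    cv = cv_subscore(inputs.get("map", np.nan), age_months, doses, map_thresholds)
    return PSofaVector(
        respiratory=resp,
        coagulation=component_score("coagulation", inputs.get("platelets", np.nan), age_months, bands),
        hepatic=component_score("hepatic", inputs.get("bilirubin", np.nan), age_months, bands),
        cardiovascular=0 if np.isnan(cv) else int(cv),
        neurological=component_score("neurological", inputs.get("gcs", np.nan), age_months, bands),
        renal=component_score("renal", inputs.get("creatinine", np.nan), age_months, bands),
    )


def secondary_labels(
    anchor_min: int, death_min: float | None, discharge_min: float
) -> dict[str, int]:
    """Optional secondary outcome flags (no model consumes these)."""
    death48 = int(death_min is not None and anchor_min < death_min <= anchor_min + 48 * 60)
    disch7 = int(death_min is None and anchor_min < discharge_min <= anchor_min + 7 * 24 * 60)
    return {"death_within_48h": death48, "discharge_within_7d": disch7}
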