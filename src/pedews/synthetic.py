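"""Synthetic paediatric-ICU cohort generator with known deterioration dynamics.

Real PICU event streams cannot be shared, so every downstream stage is
exercised on a generated cohort that emulates their load-bearing structure:

* asynchronous, multi-rate vital-sign observations (non-invasive systolic
  blood pressure ~1.5 observations/hour, the sparsest routine vital), drawn
  from an inhomogeneous Poisson process whose rate rises in a window before
  each deterioration — so "frequency of input" is a real, modulatable
  signal of clinical concern;
* mean-reverting (Ornstein-Uhlenbeck) vital-sign processes around
  age-appropriate set-points, giving realistic short-range autocorrelation
  and controllable variability;
* sparse laboratory results with extra draws around deteriorations;
* vasoactive-infusion and ventilation-status episodes; and
* injected deterioration events: a standardised mean-arterial-pressure
  decline, a lactate rise, a vasoactive start or escalation, and occasional
  death or ECMO — the exact raw observations the composite labeller needs.

Ground truth records the generator's injected events; downstream acceptance
checks compare against the labeller's output on the emitted observations,
not the injection times, to avoid circularity in boundary minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "Cohort", "generate_cohort", "prevalence_report"]

_EPOCH = pd.Timestamp("2024-01-01 00:00:00", tz="UTC")

#: MAP lower limits by age band (months) mirrored from the packaged
#: cardiovascular sub-score thresholds; set-points sit a configurable
#: margin above them so baseline noise rarely crosses.
_MAP_LL = [(0, 1, 46.0), (1, 12, 55.0), (12, 24, 60.0), (24, 60, 62.0),
           (60, 144, 65.0), (144, 12000, 67.0)]

# (set-point by age years at [0, 1, 2, 5, 12, 18], OU stationary SD)
_VITAL_BASE = {
    "hr": ([140, 130, 115, 100, 85, 75], 8.0),
    "rr": ([40, 35, 28, 24, 20, 16], 4.0),
    "spo2": ([97.5] * 6, 1.2),
    "comfort": ([17.0] * 6, 2.0),
}
_AGE_KNOTS_Y = np.array([0.0, 1.0, 2.0, 5.0, 12.0, 18.0])


@dataclass(frozen=True)
class CohortSpec:
    """Stated world of the synthetic cohort.

    Defaults were calibrated once so that with the default windowing
    (6 h lookback, 12 h horizon, hourly stride) roughly 6.9% of windows are
    positive and roughly a quarter of patients deteriorate during their
    admission, then frozen. Identical (spec, seed) pairs reproduce
    identical cohorts.
    """

    n_patients: int = 500
    seed: int = 0
    #: mixture over age bands (years, low/high) with weights
    age_dist: tuple[tuple[float, float, float], ...] = (
        (0.0, 1 / 12, 0.08), (1 / 12, 1.0, 0.24), (1.0, 2.0, 0.16),
        (2.0, 5.0, 0.20), (5.0, 12.0, 0.22), (12.0, 18.0, 0.10),
    )
    deterioration_rate: float = 0.105  # injected events per admission-day
    obs_rate_base: float = 1.48        # observations/hour for the sparsest vital (NIBP)
    obs_rate_boost: float = 2.5        # cadence multiplier in the pre-event window
    signal_strength: float = 2.5       # MAP decline at the event, in stationary SDs
    lactate_rise: float = 2.5          # mmol/l lactate rise at the event
    mortality_frac: float = 0.04       # fraction of deteriorations ending in death
    ecmo_frac: float = 0.02            # fraction of deteriorations starting ECMO
    lactate_only_frac: float = 0.3     # deteriorations without a vasoactive start
    los_median_h: float = 48.0         # length-of-stay lognormal median (hours)
    los_sigma: float = 0.6             # lognormal sigma of LOS
    pre_event_window_min: int = 720    # ramp-up window before each event
    event_earliest_min: int = 420      # no events injected before this minute
    map_margin_mmhg: float = 12.0      # MAP set-point margin above the age lower limit
    map_sd: float = 3.5                # MAP OU stationary SD

    def validate(self) -> None:
        numeric = {k: v for k, v in asdict(self).items() if isinstance(v, (int, float))}
        for k, v in numeric.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite spec parameter {k}={v}")
        for k in ("deterioration_rate", "obs_rate_base", "obs_rate_boost",
                  "signal_strength", "lactate_rise", "los_median_h"):
            if getattr(self, k) < 0:
                raise ValueError(f"{k} must be >= 0")
        for k in ("mortality_frac", "ecmo_frac", "lactate_only_frac"):
            if not 0 <= getattr(self, k) <= 1:
                raise ValueError(f"{k} must lie in [0, 1]")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")


@dataclass
class Cohort:
    """Generated tables: long events, demographics, admissions, ground truth."""

    events: pd.DataFrame
    demographics: pd.DataFrame
    admissions: pd.DataFrame
    ground_truth: pd.DataFrame
    spec: CohortSpec = field(repr=False, default=None)

    def to_csv(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("events", "demographics", "admissions", "ground_truth"):
            p = out / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        return paths


def _interp_age(knot_values: list[float], age_y: float) -> float:
    return float(np.interp(age_y, _AGE_KNOTS_Y, knot_values))


def _map_ll(age_months: float) -> float:
    for lo, hi, ll in _MAP_LL:
        if lo <= age_months < hi:
            return ll
    return _MAP_LL[-1][2]


def _ou_path(rng: np.random.Generator, times_min: np.ndarray, sd: float, tau: float = 120.0) -> np.ndarray:
    """Exact OU discretisation at irregular times; stationary start."""
    n = len(times_min)
    x = np.empty(n)
    if n == 0:
        return x
    x[0] = rng.normal(0.0, sd)
    if n > 1:
        a = np.exp(-np.diff(times_min) / tau)
        innov = rng.normal(0.0, 1.0, n - 1) * sd * np.sqrt(1.0 - a**2)
        for i in range(1, n):
            x[i] = x[i - 1] * a[i - 1] + innov[i - 1]
    return x


def _obs_times(
    rng: np.random.Generator, los_min: float, rate_per_h: float,
    boost: float, boost_windows: list[tuple[float, float]],
) -> np.ndarray:
    """Inhomogeneous Poisson observation times by thinning; one obs near admission."""
    lam_max = rate_per_h / 60.0 * max(boost, 1.0)
    n = rng.poisson(lam_max * los_min)
    t = np.sort(rng.uniform(0.0, los_min, n))
    if boost > 1.0 and len(t):
        boosted = np.zeros(len(t), bool)
        for lo, hi in boost_windows:
            boosted |= (t >= lo) & (t < hi)
        keep_p = np.where(boosted, 1.0, 1.0 / boost)
        t = t[rng.uniform(size=len(t)) < keep_p]
    first = rng.uniform(1.0, 8.0)
    return np.unique(np.concatenate([[first], t]))


def _ramp_decay(t: np.ndarray, events: list[float], width: float, tau_decay: float) -> np.ndarray:
    """Sum over events of a shape rising linearly 0->1 over [e-width, e], decaying after."""
    out = np.zeros(len(t))
    for e in events:
        rise = np.clip((t - (e - width)) / width, 0.0, 1.0)
        decay = np.where(t > e, np.exp(-(t - e) / tau_decay), 1.0)
        out += rise * decay
    return out


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full synthetic cohort; deterministic under (spec, seed)."""
    spec.validate()
    seeds = np.random.SeedSequence(spec.seed).spawn(max(spec.n_patients, 1))
    ev_frames, demo_rows, adm_rows, gt_rows = [], [], [], []
    age_bands = np.array([(lo, hi) for lo, hi, _ in spec.age_dist])
    age_w = np.array([w for *_, w in spec.age_dist], float)
    age_w = age_w / age_w.sum()

    for pidx in range(spec.n_patients):
        rng = np.random.default_rng(seeds[pidx])
        pid, aid = f"P{pidx:05d}", f"A{pidx:05d}"
        band = rng.choice(len(age_bands), p=age_w)
        age_y = rng.uniform(*age_bands[band])
        age_days = age_y * 365.25
        sex = "M" if rng.uniform() < 0.56 else "F"
        weight = _weight_for_age(age_y) * np.exp(0.13 * rng.normal())
        height = _height_for_age(age_y) * np.exp(0.04 * rng.normal())
        admit = _EPOCH + pd.Timedelta(minutes=float(np.floor(rng.uniform(0, 365 * 24 * 60))))

        los_min = float(np.clip(
            np.exp(np.log(spec.los_median_h) + spec.los_sigma * rng.normal()) * 60.0,
            3 * 60.0, 21 * 24 * 60.0))

        events_t, triggers, died_at, ecmo_at = _draw_events(rng, spec, los_min)
        if died_at is not None:
            los_min = died_at
        rows = _emit_admission(
            rng, spec, pid, aid, age_y, age_days, weight, los_min,
            events_t, triggers, ecmo_at)
        ev = pd.DataFrame(rows, columns=["minute", "variable", "value", "unit"])
        ev.insert(0, "admission_id", aid)
        ev.insert(0, "patient_id", pid)
        ev["timestamp"] = admit + pd.to_timedelta(np.round(ev["minute"] * 60.0), unit="s")
        ev_frames.append(ev[["patient_id", "admission_id", "timestamp", "variable", "value", "unit", "minute"]])

        demo_rows.append({"patient_id": pid, "sex": sex, "age_days": round(age_days, 1),
                          "weight_kg": round(weight, 2), "height_cm": round(height, 1)})
        adm_rows.append({
            "admission_id": aid, "patient_id": pid, "admit_ts": admit,
            "discharge_ts": admit + pd.Timedelta(minutes=round(los_min, 2)),
            "died_flag": int(died_at is not None),
            "ecmo_start_ts": (admit + pd.Timedelta(minutes=round(ecmo_at, 2))) if ecmo_at is not None else pd.NaT,
        })
        for e, trig in zip(events_t, triggers):
            gt_rows.append({"patient_id": pid, "admission_id": aid,
                            "event_min": round(e, 2),
                            "event_ts": admit + pd.Timedelta(minutes=round(e, 2)),
                            "trigger": trig})

    events = (pd.concat(ev_frames, ignore_index=True) if ev_frames
              else pd.DataFrame(columns=["patient_id", "admission_id", "timestamp",
                                         "variable", "value", "unit", "minute"]))
    demographics = pd.DataFrame(demo_rows, columns=["patient_id", "sex", "age_days", "weight_kg", "height_cm"])
    admissions = pd.DataFrame(adm_rows, columns=["admission_id", "patient_id", "admit_ts",
                                                 "discharge_ts", "died_flag", "ecmo_start_ts"])
    ground_truth = pd.DataFrame(gt_rows, columns=["patient_id", "admission_id", "event_min",
                                                  "event_ts", "trigger"])
    return Cohort(events, demographics, admissions, ground_truth, spec)


def _draw_events(rng, spec: CohortSpec, los_min: float):
    """Injected deterioration times (>= 8 h apart), types, and death/ECMO times."""
    los_days = los_min / (24 * 60.0)
    n_ev = rng.poisson(spec.deterioration_rate * los_days)
    lo, hi = spec.event_earliest_min, los_min - 60.0
    times: list[float] = []
    if hi > lo:
        for e in np.sort(rng.uniform(lo, hi, n_ev)):
            if not times or e - times[-1] >= 480.0:
                times.append(float(e))
    triggers, died_at, ecmo_at = [], None, None
    kept = []
    for e in times:
        u = rng.uniform()
        if u < spec.mortality_frac:
            kept.append(e)
            triggers.append("death")
            died_at = e
            break  # death is the final event
        if u < spec.mortality_frac + spec.ecmo_frac and ecmo_at is None:
            trig = "ecmo"
            ecmo_at = e
        elif rng.uniform() < spec.lactate_only_frac:
            trig = "lactate_rise"
        else:
            trig = "cv_psofa_rise"
        kept.append(e)
        triggers.append(trig)
    return kept, triggers, died_at, ecmo_at


def _emit_admission(rng, spec, pid, aid, age_y, age_days, weight, los_min,
                    events_t, triggers, ecmo_at):
    """Emit all long-format observation rows for one admission."""
    rows: list[tuple[float, str, float, str]] = []
    W = float(spec.pre_event_window_min)
    boost_windows = [(e - W, e) for e in events_t]
    age_m = age_days / 30.44
    invasive = bool(events_t) or rng.uniform() < 0.45

    # --- blood pressure: set-point a margin above the age lower limit
    map_set = _map_ll(age_m) + spec.map_margin_mmhg + rng.normal(0.0, 2.0)
    deficit_amp = spec.signal_strength * spec.map_sd

    def bp_series(alias_sys, alias_map, rate, sd):
        t = _obs_times(rng, los_min, rate, spec.obs_rate_boost, boost_windows)
        deficit = deficit_amp * _ramp_decay(t, events_t, W, 240.0)
        mapv = map_set + _ou_path(rng, t, sd) - deficit
        mapv = np.maximum(mapv, 18.0)
        sysv = mapv * 1.45 + rng.normal(0.0, 2.0, len(t))
        for ti, m, s in zip(t, mapv, sysv):
            rows.append((ti, alias_map, round(float(m), 1), "mmHg"))
            rows.append((ti, alias_sys, round(float(s), 1), "mmHg"))

    bp_series("nibp_sys", "nibp_map", spec.obs_rate_base, spec.map_sd)
    if invasive:
        bp_series("abp_sys", "abp_map", spec.obs_rate_base * 1.4, spec.map_sd * 0.9)

    # --- other vitals
    hr_amp = {"hr": 0.8, "rr": 0.5, "spo2": -1.2, "comfort": -1.0}
    rates = {"hr": 2.0, "rr": 1.6, "spo2": 2.0, "comfort": 0.6}
    clip = {"spo2": (50.0, 100.0), "comfort": (6.0, 30.0)}
    for var, (knots, sd) in _VITAL_BASE.items():
        t = _obs_times(rng, los_min, rates[var], spec.obs_rate_boost, boost_windows)
        setp = _interp_age(knots, age_y) * (1.0 + rng.normal(0.0, 0.04))
        shape = _ramp_decay(t, events_t, W, 240.0)
        vals = setp + _ou_path(rng, t, sd) + hr_amp[var] * spec.signal_strength * sd * shape
        if var in clip:
            vals = np.clip(vals, *clip[var])
        alias = {"hr": "hr_monitor", "rr": "rr_monitor", "spo2": "spo2_monitor",
                 "comfort": "comfort_score"}[var]
        unit = {"hr": "bpm", "rr": "breaths/min", "spo2": "%", "comfort": "score"}[var]
        for ti, v in zip(t, vals):
            rows.append((ti, alias, round(float(v), 1), unit))

    # capillary refill: slow baseline, prolongs before events
    t = _obs_times(rng, los_min, 0.5, spec.obs_rate_boost, boost_windows)
    crt = 1.5 + 1.5 * _ramp_decay(t, events_t, W, 240.0) + np.abs(rng.normal(0.0, 0.3, len(t)))
    for ti, v in zip(t, crt):
        rows.append((ti, "crt_assessment", round(float(v), 1), "s"))

    # --- labs
    lac_base = max(0.5, 1.0 + 0.15 * rng.normal())
    t_lac = list(np.cumsum(rng.exponential(480.0, max(int(los_min / 480.0) + 3, 3))))
    for e in events_t:  # clinician draws gases around deteriorations
        t_lac += [e - 30.0, e + 30.0, e + 120.0]
    t_lac = np.unique(np.clip(np.array([ti for ti in t_lac if 5.0 <= ti < los_min]), 5.0, los_min - 1))
    if len(t_lac) == 0:
        t_lac = np.array([min(30.0, los_min / 2)])
    lac_shape = _ramp_decay(t_lac, events_t, W, 600.0)
    lac = np.maximum(0.3, lac_base + 0.12 * rng.normal(0.0, 1.0, len(t_lac)) + spec.lactate_rise * lac_shape)
    for ti, v in zip(t_lac, lac):
        rows.append((ti, "lactate_blood", round(float(v), 2), "mmol/l"))

    daily = {"platelets_lab": (250.0 * np.exp(0.25 * rng.normal()), -0.25, 5.0, "10^9/l"),
             "bilirubin_lab": (12.0 * np.exp(0.5 * rng.normal()), 0.6, 1.0, "umol/l"),
             "creatinine_lab": (28.0 + 2.6 * age_y, 0.35, 2.0, "umol/l"),
             "sodium_lab": (140.0, 0.01, 2.2, "mmol/l")}
    for alias, (base, ev_mult, noise_sd, unit) in daily.items():
        t = np.cumsum(rng.exponential(1440.0, max(int(los_min / 1440.0) + 2, 2)))
        t = np.concatenate([[rng.uniform(30.0, 180.0)], t])
        t = np.unique(t[t < los_min - 1])
        shape = _ramp_decay(t, events_t, W, 900.0)
        vals = base * (1.0 + ev_mult * 0.3 * shape) + rng.normal(0.0, noise_sd, len(t))
        for ti, v in zip(t, np.maximum(vals, 1.0)):
            rows.append((ti, alias, round(float(v), 1), unit))

    # --- ventilation episodes and FiO2
    ventilated = invasive and rng.uniform() < 0.75
    gcs_base = 15.0
    if ventilated:
        gcs_base = rng.uniform(7.0, 11.0)
        t_wean = los_min * rng.uniform(0.6, 0.85)
        rows.append((2.0, "vent_status", 3.0, "ordinal"))
        rows.append((t_wean, "vent_status", 2.0, "ordinal"))
        if t_wean + 360 < los_min:
            rows.append((t_wean + 360.0, "vent_status", 0.0, "ordinal"))
        t_f = np.arange(5.0, los_min, 240.0)
        fio2 = np.clip(0.35 + 0.15 * _ramp_decay(t_f, events_t, W, 240.0)
                       + rng.normal(0.0, 0.03, len(t_f)), 0.21, 1.0)
        for ti, v in zip(t_f, fio2):
            if ti < (t_wean + 360.0):
                rows.append((ti, "fio2_device", round(float(v), 2), "fraction"))
    elif rng.uniform() < 0.2:
        rows.append((3.0, "vent_status", 2.0, "ordinal"))  # high-flow from admission
        stop = los_min * rng.uniform(0.3, 0.9)
        rows.append((stop, "vent_status", 0.0, "ordinal"))
    for ti in np.arange(60.0, los_min, 1440.0):
        rows.append((ti, "gcs_assessment", float(np.clip(round(gcs_base + rng.normal(0, 0.8)), 3, 15)), "score"))

    # --- vasoactive infusions: start at the event, escalate if already running
    active: dict[str, float] = {}
    for e, trig in zip(events_t, triggers):
        if trig == "lactate_rise":
            continue
        if trig == "ecmo":
            drug, dose = "epinephrine_rate", round(rng.uniform(0.15, 0.3), 3)
        elif active:
            drug = next(iter(active))  # escalate the running infusion across a band edge
            prior = active[drug]
            dose = (round(max(prior * 1.8, 16.0), 2) if drug == "dopamine_rate"
                    else round(max(prior * 2.0, 0.12), 3))
        elif rng.uniform() < 0.6:
            drug, dose = "dopamine_rate", round(rng.uniform(6.0, 12.0), 2)
        else:
            drug, dose = "epinephrine_rate", round(rng.uniform(0.03, 0.09), 3)
        rows.append((e, drug, dose, "ug/kg/min"))
        active[drug] = dose
        stop = e + 1440.0
        later = [x for x in events_t if x > e]
        if (not later or later[0] > stop) and stop < los_min:
            rows.append((stop, drug, 0.0, "ug/kg/min"))
            active.pop(drug, None)

    return [(ti, var, val, unit) for ti, var, val, unit in rows if 0.0 <= ti < los_min]


def _weight_for_age(age_y: float) -> float:
    knots = [3.4, 9.5, 12.0, 18.3, 38.0, 61.0]
    return _interp_age(knots, age_y)


def _height_for_age(age_y: float) -> float:
    knots = [50.0, 75.0, 86.0, 109.0, 150.0, 172.0]
    return _interp_age(knots, age_y)


def prevalence_report(ground_truth: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Per-horizon positive window fractions with per-trigger breakdowns.

    ``labels`` is a labels table with columns (horizon_h, label, trigger);
    each window counts once, under its first-firing trigger.
    """
    out = []
    for h, sub in labels.groupby("horizon_h"):
        row = {"horizon_h": h, "n_windows": len(sub),
               "n_positive": int(sub["label"].sum()),
               "positive_fraction": float(sub["label"].mean()) if len(sub) else 0.0}
        for trig in ("cv_rise", "lactate", "ecmo", "death"):
            row[f"n_{trig}"] = int((sub["trigger"] == trig).sum())
        out.append(row)
    report = pd.DataFrame(out)
    report.attrs["n_ground_truth_events"] = len(ground_truth)
    return report
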