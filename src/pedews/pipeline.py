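"""End-to-end orchestration: simulate -> featurize -> label -> train -> evaluate -> explain.

The stages are plain library functions over in-memory tables; ``run`` wires
them behind one configuration, optionally persisting each stage's artefacts
as CSV (with a config-fingerprint sidecar so unchanged stages are skipped).
Structured log lines record row counts at every filter so consolidation
drops, short-admission exclusions and imputation counts are auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import grid as G
from . import outcomes as O
from .config import PipelineConfig
from .errors import ConfigurationError
from .evaluation import EvalReport, evaluate_scores, repeated_eval
from .explain import attribute, internal_importance, patient_timeline
from .features import VIS_COEFFICIENTS, VariableMap, consolidate
from .models import (RiskModel, SearchConfig, fit_psofa_comparator,
                     predict, split_patients, tune_and_fit)
from .references import ReferenceSet, centile_normalise, default_reference_dir, growth_zscore
from .synthetic import Cohort, generate_cohort, prevalence_report
from .windows import FeatureRegistry, WindowSpec, summarise_windows, window_anchors

__all__ = ["FeaturisedCohort", "featurize_cohort", "label_cohort", "run", "PipelineResult"]

_DOSE_FEATURES = tuple(VIS_COEFFICIENTS)


def _load_tables(config: PipelineConfig):
    ref_dir = Path(config.reference_dir) if config.reference_dir else default_reference_dir()
    refs = ReferenceSet.load(ref_dir)
    vmap = VariableMap.from_csv(config.variable_map or ref_dir / "variable_map.csv")
    policy = G.ImputationPolicy.from_csv(config.imputation_policy or ref_dir / "imputation_policy.csv")
    catalogue = pd.read_csv(ref_dir / "catalogue.csv")
    return refs, vmap, policy, catalogue


@dataclass
class AdmissionSeries:
    """Per-admission minute-grid state kept for labelling and timelines."""

    admission_id: str
    patient_id: str
    age_days: float
    los_min: int
    anchors: np.ndarray
    cv: np.ndarray = field(repr=False, default=None)
    lactate: np.ndarray = field(repr=False, default=None)
    death_min: float | None = None
    ecmo_min: float | None = None


@dataclass
class FeaturisedCohort:
    """Model-ready windows plus everything needed downstream.

    ``X`` is the raw (unscaled) wide feature matrix, row-aligned with
    ``meta`` (patient, admission, anchor); ``psofa`` carries the comparator
    features. Scaling is fitted on the training split at train time.
    """

    X: pd.DataFrame
    psofa: pd.DataFrame
    meta: pd.DataFrame
    registry: FeatureRegistry
    admissions: dict[str, AdmissionSeries]
    log: list[str] = field(default_factory=list)

    def sidecar(self) -> dict:
        return {"columns": self.registry.columns.to_dict(orient="records")}


def _minutes_from_admit(events: pd.DataFrame, admissions: pd.DataFrame) -> pd.DataFrame:
    if "minute" in events.columns:
        return events
    admit = admissions.set_index("admission_id")["admit_ts"]
    ts = pd.to_datetime(events["timestamp"], utc=True)
    base = events["admission_id"].map(admit)
    return events.assign(minute=(ts - base).dt.total_seconds() / 60.0)


def _training_medians(
    consolidated: pd.DataFrame, demographics: pd.DataFrame, policy: G.ImputationPolicy,
    train_patients: set[str], log: list[str],
) -> dict[str, float | np.ndarray]:
    """Cohort medians from observed training values only (leakage guard)."""
    age = demographics.set_index("patient_id")["age_days"]
    df = consolidated.assign(age_days=consolidated["patient_id"].map(age))
    train = df[df["patient_id"].isin(train_patients)]
    if len(train) == 0:
        train = df
        log.append("medians: no training rows; falling back to whole cohort")
    medians: dict[str, float | np.ndarray] = {}
    n_bins = len(G.AGE_BIN_EDGES_DAYS) - 1
    for feature, (strategy, _) in policy.strategies.items():
        vals = train.loc[train["variable"] == feature, ["value", "age_days"]]
        if strategy == "global_median":
            pool = vals["value"] if len(vals) else df.loc[df["variable"] == feature, "value"]
            if len(pool) == 0:
                raise ConfigurationError(f"no observed values anywhere for feature {feature!r}")
            medians[feature] = float(pool.median())
        elif strategy == "age_stratified_median":
            if len(vals) == 0:
                raise ConfigurationError(f"no observed training values for {feature!r}")
            bins = np.searchsorted(G.AGE_BIN_EDGES_DAYS, vals["age_days"].to_numpy(), side="right") - 1
            overall = float(vals["value"].median())
            per_bin = np.full(n_bins, overall)
            for b, sub in vals.groupby(bins):
                per_bin[int(b)] = float(sub["value"].median())
            medians[feature] = per_bin
    return medians


def _component_series(component: str, values: np.ndarray, age_months: float,
                      bands: pd.DataFrame) -> np.ndarray:
    """Vectorised minute-wise band score for one non-cardiovascular system."""
    sub = bands[(bands["component"] == component)
                & (bands["age_low_months"] <= age_months)
                & (age_months < bands["age_high_months"])]
    score = np.zeros(len(values))
    v = np.asarray(values, float)
    with np.errstate(invalid="ignore"):
        for row in sub.itertuples(index=False):
            hit = (v < row.threshold if row.direction == "lt"
                   else v <= row.threshold if row.direction == "le"
                   else v >= row.threshold)
            score = np.where(hit & ~np.isnan(v), np.maximum(score, row.score), score)
    return score


def featurize_cohort(
    cohort: Cohort, config: PipelineConfig, train_patients: set[str],
) -> FeaturisedCohort:
    """Grid, impute, window and summarise every admission.

    ``train_patients`` restricts imputation medians to the training split.
    Admissions shorter than the lookback are excluded (logged).
    """
    refs, vmap, policy, catalogue = _load_tables(config)
    spec: WindowSpec = config.window
    log: list[str] = []

    events = _minutes_from_admit(cohort.events, cohort.admissions)
    cons = consolidate(events[["patient_id", "admission_id", "timestamp", "variable",
                               "value", "unit", "minute"]], vmap, log=log)
    cons = cons.merge(events[["patient_id", "admission_id", "timestamp", "minute"]].drop_duplicates(),
                      on=["patient_id", "admission_id", "timestamp"], how="left")
    medians = _training_medians(cons, cohort.demographics, policy, train_patients, log)

    ts_features = catalogue.loc[catalogue["kind"] == "timeseries", "feature"].tolist()
    lab_features = catalogue.loc[catalogue["kind"] == "lab", "feature"].tolist()
    centile_var = dict(zip(catalogue["feature"], catalogue["centile_variable"]))
    demo = cohort.demographics.set_index("patient_id")

    frames_X, frames_psofa, meta_rows = [], [], []
    adm_state: dict[str, AdmissionSeries] = {}
    n_short = 0
    by_adm = dict(list(cons.groupby("admission_id")))

    for adm in cohort.admissions.itertuples(index=False):
        los_min = int(np.floor((adm.discharge_ts - adm.admit_ts).total_seconds() / 60.0))
        anchors = window_anchors(los_min, spec)
        d = demo.loc[adm.patient_id]
        age_days = float(d["age_days"])
        age_months = age_days / 30.44
        death_min = float(los_min) if adm.died_flag else None
        ecmo_min = (None if pd.isna(adm.ecmo_start_ts)
                    else (adm.ecmo_start_ts - adm.admit_ts).total_seconds() / 60.0)
        state = AdmissionSeries(adm.admission_id, adm.patient_id, age_days,
                                los_min, anchors, death_min=death_min, ecmo_min=ecmo_min)
        if len(anchors) == 0:
            n_short += 1
            adm_state[adm.admission_id] = state
            continue

        sub = by_adm.get(adm.admission_id, cons.iloc[0:0])
        per_var = {v: g for v, g in sub.groupby("variable")}

        def gridded(feature: str, lab: bool) -> G.GriddedSeries:
            g = per_var.get(feature)
            minutes = g["minute"].to_numpy() if g is not None else np.empty(0)
            values = g["value"].to_numpy() if g is not None else np.empty(0)
            s = G.to_minute_grid(minutes, values, los_min, feature, log=log)
            s = G.carry_forward_labs(s) if lab else G.interpolate(s)
            return G.impute(s, policy, age_days, medians)

        series = {f: gridded(f, lab=False) for f in ts_features if f not in ("vis", "sf_ratio")}
        labs = {f: gridded(f, lab=True) for f in lab_features}
        # infusions are step functions: carry each dose until the next change
        doses = {}
        for drug in _DOSE_FEATURES:
            g = per_var.get(drug)
            s = G.to_minute_grid(g["minute"].to_numpy() if g is not None else np.empty(0),
                                 g["value"].to_numpy() if g is not None else np.empty(0),
                                 los_min, drug, log=log)
            s = G.carry_forward_labs(s, max_carry_min=los_min + 1)
            doses[drug] = G.impute(s, policy, age_days, medians)

        # derived series: VIS and the SpO2:FiO2 ratio
        vis_vals = sum(VIS_COEFFICIENTS[k] * doses[k].values for k in _DOSE_FEATURES)
        vis_prov = np.maximum.reduce([np.where(doses[k].provenance == G.OBSERVED, G.OBSERVED, G.IMPUTED)
                                      for k in _DOSE_FEATURES])
        series["vis"] = G.GriddedSeries("vis", vis_vals, vis_prov)
        if "vis" in ts_features:
            pass
        spo2, fio2 = series["spo2"], series["fio2"]
        sf = np.clip(spo2.values / np.maximum(fio2.values, 0.21), 0.0, 500.0)
        series["sf_ratio"] = G.GriddedSeries("sf_ratio", sf, spo2.provenance.copy())

        # outcome series on RAW values (normalisation must not move the label)
        cv = O.cv_subscore_series(series["map"].values,
                                  {k: doses[k].values for k in _DOSE_FEATURES},
                                  age_months, refs.psofa_map)
        state.cv = cv
        state.lactate = labs["lactate"].values.copy()

        # organ-dysfunction comparator series
        comp = {
            "respiratory": np.minimum(
                _component_series("respiratory", series["sf_ratio"].values, age_months, refs.psofa_bands),
                np.where(series["vent_level"].values >= 2, 4, 2)),
            "coagulation": _component_series("coagulation", labs["platelets"].values, age_months, refs.psofa_bands),
            "hepatic": _component_series("hepatic", labs["bilirubin"].values, age_months, refs.psofa_bands),
            "cardiovascular": np.nan_to_num(cv),
            "neurological": _component_series("neurological", labs["gcs"].values, age_months, refs.psofa_bands),
            "renal": _component_series("renal", labs["creatinine"].values, age_months, refs.psofa_bands),
        }

        # age normalisation of centile-mapped vitals, after outcome scoring
        if config.age_normalise:
            for f in ts_features:
                cv_var = centile_var.get(f)
                if isinstance(cv_var, str) and cv_var:
                    s = series[f]
                    probs, grid_vals = refs.centiles.grid(cv_var, age_days, str(d["sex"]))
                    series[f] = G.GriddedSeries(f, np.interp(s.values, grid_vals, probs), s.provenance)

        cols: dict[str, np.ndarray] = {}
        for f in ts_features:
            stats = summarise_windows(series[f], anchors, spec)
            for j, stat in enumerate(("mean", "sd", "slope", "r2", "freq", "latest")):
                cols[f"{f}__{stat}"] = stats[:, j]
        for f in lab_features:
            cols[f"{f}__latest"] = labs[f].values[anchors - 1]
        wz = growth_zscore("weight", float(d["weight_kg"]), age_days, str(d["sex"]), refs.lms)
        hz = growth_zscore("height", float(d["height_cm"]), age_days, str(d["sex"]), refs.lms)
        statics = {"age_years": age_days / 365.25, "sex_male": float(d["sex"] == "M"),
                   "weight_z": wz, "height_z": hz}
        for k, v in statics.items():
            cols[k] = np.full(len(anchors), v)
        frames_X.append(pd.DataFrame(cols))

        pcols: dict[str, np.ndarray] = {}
        total_latest = np.zeros(len(anchors))
        for name, arr in comp.items():
            s = G.GriddedSeries(f"psofa_{name}", arr, np.full(los_min, G.OBSERVED, np.uint8))
            stats = summarise_windows(s, anchors, spec)
            pcols[f"psofa_{name}__latest"] = stats[:, 5]
            pcols[f"psofa_{name}__mean"] = stats[:, 0]
            pcols[f"psofa_{name}__sd"] = stats[:, 1]
            total_latest += stats[:, 5]
        pcols["psofa_total__latest"] = total_latest
        frames_psofa.append(pd.DataFrame(pcols))

        meta_rows.append(pd.DataFrame({
            "patient_id": adm.patient_id, "admission_id": adm.admission_id,
            "anchor_min": anchors}))
        adm_state[adm.admission_id] = state

    if n_short:
        log.append(f"featurize: excluded {n_short} admissions shorter than the "
                   f"{spec.lookback_h:g} h lookback")
    if frames_X:
        X = pd.concat(frames_X, ignore_index=True)
        psofa = pd.concat(frames_psofa, ignore_index=True)
        meta = pd.concat(meta_rows, ignore_index=True)
    else:
        X, psofa = pd.DataFrame(), pd.DataFrame()
        meta = pd.DataFrame(columns=["patient_id", "admission_id", "anchor_min"])

    reg_rows = []
    for c in X.columns:
        if "__" in c:
            feat, stat = c.rsplit("__", 1)
            kind = "lab" if feat in lab_features else "timeseries"
        else:
            feat, stat, kind = c, "static", "static"
        reg_rows.append({"column": c, "feature": feat, "stat": stat, "kind": kind})
    registry = FeatureRegistry(pd.DataFrame(reg_rows))
    return FeaturisedCohort(X, psofa, meta, registry, adm_state, log)


def label_cohort(feat: FeaturisedCohort, config: PipelineConfig) -> pd.DataFrame:
    """Composite deterioration labels for every window, row-aligned with X."""
    spec = config.window
    out = []
    for aid, sub in feat.meta.groupby("admission_id", sort=False):
        st = feat.admissions[aid]
        lab = O.label_admission(
            sub["anchor_min"].to_numpy(), spec.lookback_min, spec.horizon_min,
            st.cv, st.lactate, st.los_min, st.death_min, st.ecmo_min,
            config.lactate_threshold_mmol_l, config.cv_rise_baseline)
        lab.insert(0, "admission_id", aid)
        lab.insert(0, "patient_id", st.patient_id)
        out.append(lab)
    out = [f for f in out if len(f)]
    if not out:
        return pd.DataFrame(columns=["patient_id", "admission_id", "anchor_min",
                                     "horizon_h", "label", "trigger", "trigger_min"])
    labels = pd.concat(out, ignore_index=True)
    # meta is grouped per admission in order, so realign defensively by keys
    assert len(labels) == len(feat.meta)
    return labels


@dataclass
class PipelineResult:
    cohort: Cohort
    features: FeaturisedCohort
    labels: pd.DataFrame
    split: object = None
    scaler: G.PercentileScaler | None = None
    models: dict = field(default_factory=dict)
    reports: dict[str, EvalReport] = field(default_factory=dict)
    results_table: pd.DataFrame | None = None
    prevalence: pd.DataFrame | None = None
    explain: dict = field(default_factory=dict)


_STAGES = ("simulate", "featurize", "label", "train", "evaluate", "explain", "all")


def run(stage: str, config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute pipeline stages up to and including ``stage``.

    With ``out_dir`` set, per-stage CSV artefacts are written and a
    fingerprint sidecar makes repeated runs with an unchanged configuration
    skip the simulate stage's rewrite. Stages are cumulative: asking for a
    later stage runs its dependencies.
    """
    if stage not in _STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    upto = _STAGES.index(stage) if stage != "all" else len(_STAGES) - 2
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    cohort = generate_cohort(config.cohort)
    if out is not None:
        marker = out / "fingerprint.json"
        fp = {"config": config.fingerprint()}
        if not (marker.exists() and json.loads(marker.read_text()) == fp and (out / "events.csv").exists()):
            cohort.to_csv(out)
            marker.write_text(json.dumps(fp))
    result = PipelineResult(cohort=cohort, features=None, labels=None)
    if upto < 1:
        return result

    split = split_patients(cohort.demographics["patient_id"], config.fractions, config.seed)
    result.split = split
    feat = featurize_cohort(cohort, config, set(split.patients("train")))
    result.features = feat
    if out is not None:
        feat.X.assign(**{c: feat.meta[c] for c in feat.meta.columns}).to_csv(out / "features.csv", index=False)
        (out / "features.json").write_text(json.dumps(feat.sidecar()))
    if upto < 2:
        return result

    labels = label_cohort(feat, config)
    result.labels = labels
    result.prevalence = prevalence_report(cohort.ground_truth, labels)
    if out is not None:
        labels.to_csv(out / "labels.csv", index=False)
    if upto < 3:
        return result

    is_train = (split.window_split(feat.meta["patient_id"]) == "train").to_numpy()
    scaler = G.PercentileScaler().fit(feat.X[is_train])
    Xs = scaler.transform(feat.X)
    y = labels["label"].to_numpy()
    groups = feat.meta["patient_id"].to_numpy()
    result.scaler = scaler
    gbdt = tune_and_fit(Xs[is_train], y[is_train], groups[is_train], "gbdt",
                        config.search, seed=config.seed)
    logit = tune_and_fit(Xs[is_train], y[is_train], groups[is_train], "logistic_l2",
                         config.search, seed=config.seed)
    result.models = {"gbdt": gbdt, "logistic_l2": logit}
    if upto < 4:
        return result

    rows = []
    for name, model in result.models.items():
        m = evaluate_scores(predict(model, Xs[~is_train]), y[~is_train], config.recall_setpoint)
        rows.append({"family": name, **m})
    for variant in ("summary", "components", "components_mean_var"):
        comp = fit_psofa_comparator(variant, "logistic", feat.psofa[is_train], y[is_train],
                                    seed=config.seed)
        m = evaluate_scores(predict(comp, feat.psofa.loc[~is_train, comp.feature_names]),
                            y[~is_train], config.recall_setpoint)
        rows.append({"family": f"psofa_{variant}_lr", **m})
        result.models[f"psofa_{variant}"] = comp
    result.results_table = pd.DataFrame(rows)
    if out is not None:
        result.results_table.to_csv(out / "results.csv", index=False)
        result.prevalence.to_csv(out / "prevalence.csv", index=False)
    if upto < 5:
        return result

    imp = internal_importance(gbdt)
    att = attribute(gbdt, Xs[~is_train].head(200))
    # one illustrative timeline: the test admission with the most windows
    test_meta = feat.meta[~is_train]
    aid = test_meta.groupby("admission_id").size().idxmax() if len(test_meta) else None
    if aid is not None:
        rows_a = (feat.meta["admission_id"] == aid).to_numpy()
        timeline, drivers = patient_timeline(gbdt, Xs[rows_a],
                                             feat.meta.loc[rows_a, "anchor_min"].to_numpy())
    else:
        timeline, drivers = pd.DataFrame(), pd.DataFrame()
    result.explain = {"importance": imp, "attribution": att,
                      "timeline": timeline, "drivers": drivers, "admission_id": aid}
    if out is not None:
        imp.to_csv(out / "importance.csv", index=False)
        timeline.to_csv(out / "timeline.csv", index=False)
    return result
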