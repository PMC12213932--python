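"""Risk models: gradient-boosted trees, L2 logistic regression, comparators.

Patients are randomised to train/test sets with every window of a patient
staying in one set (an 85/15 split by default). Hyperparameters are chosen
by an adaptive search over patient-grouped 4-fold cross-validation,
maximising out-of-fold AUPRC, with the positive-class weight among the
searched parameters; the winning configuration is refit on the full
training split. Organ-dysfunction comparator models (total score only, the
six sub-scores, or sub-scores plus their window mean and variability) share
the same surface.

The gradient-boosted family is scikit-learn's GradientBoostingClassifier;
its per-tree structures are what the interpretability module traverses.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.metrics import average_precision_score

from .errors import RegistryMismatchError

__all__ = [
    "SplitPlan", "SearchConfig", "RiskModel",
    "split_patients", "tune_and_fit", "fit_psofa_comparator", "predict",
    "DEFAULT_SPACES", "PSOFA_COMPONENTS",
]

PSOFA_COMPONENTS = ("respiratory", "coagulation", "hepatic",
                    "cardiovascular", "neurological", "renal")

#: searched hyperparameter spaces; ("log"/"lin", low, high), ("int", low, high)
#: or ("choice", options). Bounds are repo defaults (documented in the
#: methods note); the positive-class weight is always searched.
DEFAULT_SPACES: dict[str, dict[str, tuple]] = {
    "gbdt": {
        "n_estimators": ("int", 60, 200),
        "learning_rate": ("log", 0.05, 0.3),
        "max_depth": ("choice", (2, 3, 4)),
        "subsample": ("lin", 0.5, 0.9),
        "max_features": ("lin", 0.15, 0.6),
        "min_samples_leaf": ("int", 5, 60),
        "pos_weight": ("log", 0.5, 20.0),
    },
    "logistic_l2": {
        "C": ("log", 1e-3, 100.0),
        "pos_weight": ("log", 0.5, 20.0),
    },
}


@dataclass(frozen=True)
class SplitPlan:
    """patient -> split name; windows inherit their patient's split."""

    assignments: pd.Series  # index patient_id, values split names
    seed: int

    def patients(self, split: str) -> list[str]:
        return self.assignments.index[self.assignments == split].tolist()

    def window_split(self, patient_ids: pd.Series) -> pd.Series:
        return patient_ids.map(self.assignments)


def split_patients(
    patient_ids, fractions: dict[str, float] | None = None, seed: int = 0
) -> SplitPlan:
    """Randomise patients to disjoint sets; deterministic under seed.

    Set sizes are within +-1 patient of the target fractions (largest-
    remainder apportionment over a seeded shuffle).
    """
    fractions = fractions or {"train": 0.85, "test": 0.15}
    ids = pd.Index(patient_ids).unique().sort_values()
    if len(ids) < 2:
        raise ValueError("need at least 2 patients to split")
    for name, f in fractions.items():
        if f <= 0:
            raise ValueError(f"requested split {name!r} has fraction {f}")
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    shuffled = ids.to_numpy()[rng.permutation(len(ids))]
    names = list(fractions)
    quotas = np.array([fractions[n] * len(ids) for n in names])
    counts = np.floor(quotas).astype(int)
    remainder = len(ids) - counts.sum()
    for i in np.argsort(-(quotas - counts))[:remainder]:
        counts[i] += 1
    labels = np.repeat(names, counts)
    return SplitPlan(pd.Series(labels, index=pd.Index(shuffled, name="patient_id")), seed)


@dataclass(frozen=True)
class SearchConfig:
    """Adaptive hyperparameter search settings (objective: out-of-fold AUPRC)."""

    n_folds: int = 4
    budget: int = 20
    seed: int = 0
    space: dict[str, tuple] | None = None  # None -> family default

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise ValueError("search budget must be >= 1")


def _registry_hash(feature_names: list[str]) -> str:
    return hashlib.md5("\x1f".join(feature_names).encode()).hexdigest()


@dataclass
class RiskModel:
    """A fitted (or fit-ready) windowed risk model.

    ``predict`` refuses feature matrices whose columns do not match the
    registry hash captured at fit time. Output contract: probability of
    deterioration within the horizon, in [0, 1].
    """

    family: str  # gbdt | logistic_l2 | psofa_comparator
    params: dict = field(default_factory=dict)
    search: SearchConfig | None = None
    seed: int = 0
    estimator: object = field(default=None, repr=False)
    feature_names: list[str] | None = None
    registry_hash: str | None = None
    best_params: dict | None = None

    def fit(self, X: pd.DataFrame, y, groups=None) -> "RiskModel":
        if self.search is not None:
            fitted = tune_and_fit(X, y, groups, self.family, self.search, seed=self.seed)
            self.__dict__.update(fitted.__dict__)
            return self
        self.estimator = _build_estimator(self.family, self.params, self.seed)
        w = _sample_weights(y, self.params.get("pos_weight", 1.0))
        self.estimator.fit(X.to_numpy(float), np.asarray(y, int), sample_weight=w)
        self.feature_names = list(X.columns)
        self.registry_hash = _registry_hash(self.feature_names)
        self.best_params = dict(self.params)
        return self


def _sample_weights(y, pos_weight: float) -> np.ndarray:
    y = np.asarray(y, int)
    return np.where(y == 1, float(pos_weight), 1.0)


def _build_estimator(family: str, params: dict, seed: int):
    p = {k: v for k, v in params.items() if k != "pos_weight"}
    if family == "gbdt":
        return GradientBoostingClassifier(random_state=seed, **p)
    if family in ("logistic_l2", "psofa_comparator"):
        # scikit-learn's default penalty is the L2 (ridge) weight penalty
        return LogisticRegression(solver="lbfgs", max_iter=5000, random_state=seed, **p)
    raise ValueError(f"unknown model family {family!r}")


def _sample_params(space: dict[str, tuple], rng: np.random.Generator) -> dict:
    out = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "log":
            out[name] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        elif kind == "lin":
            out[name] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "int":
            out[name] = int(rng.integers(spec[1], spec[2] + 1))
        elif kind == "choice":
            out[name] = spec[1][rng.integers(len(spec[1]))]
        else:
            raise ValueError(f"bad space entry {name}: {spec}")
    return out


def _perturb_params(base: dict, space: dict[str, tuple], rng: np.random.Generator) -> dict:
    """Gaussian move around a good configuration (adaptive exploitation step)."""
    out = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "choice":
            out[name] = (spec[1][rng.integers(len(spec[1]))]
                         if rng.uniform() < 0.25 else base[name])
            continue
        lo, hi = spec[1], spec[2]
        if kind == "log":
            z = np.log(base[name]) + rng.normal(0, 0.25 * (np.log(hi) - np.log(lo)))
            val = float(np.exp(np.clip(z, np.log(lo), np.log(hi))))
        else:
            z = base[name] + rng.normal(0, 0.25 * (hi - lo))
            val = float(np.clip(z, lo, hi))
        out[name] = int(round(val)) if kind == "int" else val
    return out


def _fold_indices(y: np.ndarray, groups: np.ndarray, n_folds: int, seed: int):
    """Patient-grouped folds stratified by patient outcome; no patient in two folds."""
    cv = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros(len(y)), y, groups))


def tune_and_fit(
    X: pd.DataFrame, y, groups, family: str,
    search: SearchConfig | None = None, seed: int = 0,
) -> RiskModel:
    """Adaptive search on mean out-of-fold AUPRC, then refit on the full split.

    The first third of the budget samples the space at random; later trials
    perturb a configuration drawn from the best 30% so far. Deterministic
    under (search.seed, seed).
    """
    search = search or SearchConfig()
    space = search.space or DEFAULT_SPACES[family if family in DEFAULT_SPACES else "logistic_l2"]
    Xa = X.to_numpy(float)
    ya = np.asarray(y, int)
    ga = np.asarray(groups if groups is not None else np.arange(len(ya)))
    n_folds = min(search.n_folds, len(np.unique(ga)))
    folds = _fold_indices(ya, ga, n_folds, search.seed)
    rng = np.random.default_rng(search.seed)

    trials: list[tuple[float, dict]] = []
    n_random = max(4, search.budget // 3)
    for t in range(search.budget):
        if t < n_random or len(trials) == 0:
            params = _sample_params(space, rng)
        else:
            top = sorted(trials, key=lambda kv: -kv[0])[:max(1, int(0.3 * len(trials)))]
            params = _perturb_params(top[rng.integers(len(top))][1], space, rng)
        scores = []
        for tr, te in folds:
            if ya[te].min() == ya[te].max():
                continue  # degenerate fold carries no ranking information
            est = _build_estimator(family, params, seed)
            est.fit(Xa[tr], ya[tr], sample_weight=_sample_weights(ya[tr], params.get("pos_weight", 1.0)))
            scores.append(average_precision_score(ya[te], est.predict_proba(Xa[te])[:, 1]))
        trials.append((float(np.mean(scores)) if scores else -np.inf, params))

    best_score, best_params = max(trials, key=lambda kv: kv[0])
    model = RiskModel(family=family, params=best_params, seed=seed)
    model.fit(X, y)
    model.best_params = dict(best_params) | {"oof_auprc": best_score}
    return model


def fit_psofa_comparator(
    variant: str, link: str, psofa_features: pd.DataFrame, y,
    groups=None, search: SearchConfig | None = None, seed: int = 0,
) -> RiskModel:
    """Comparator on organ-dysfunction scores alone.

    variant: "summary" (total score, 1 predictor), "components" (six
    sub-scores), or "components_mean_var" (sub-scores plus their window
    mean and SD, 18 predictors). link: "logistic" or "gbdt".
    """
    if variant == "summary":
        cols = ["psofa_total__latest"]
    elif variant == "components":
        cols = [f"psofa_{c}__latest" for c in PSOFA_COMPONENTS]
    elif variant == "components_mean_var":
        cols = [f"psofa_{c}__{s}" for s in ("latest", "mean", "sd") for c in PSOFA_COMPONENTS]
    else:
        raise ValueError(f"unknown comparator variant {variant!r}")
    missing = [c for c in cols if c not in psofa_features.columns]
    if missing:
        raise RegistryMismatchError(f"comparator variant {variant!r} missing columns {missing}")
    X = psofa_features[cols]
    family = "gbdt" if link == "gbdt" else "logistic_l2"
    if search is None:
        model = RiskModel(family=family, params={"C": 1.0} if family == "logistic_l2" else
                          {"n_estimators": 150, "max_depth": 3, "learning_rate": 0.1}, seed=seed)
        model.fit(X, y)
    else:
        model = tune_and_fit(X, y, groups, family, search, seed=seed)
    model.family = "psofa_comparator"
    return model


def predict(model: RiskModel, X: pd.DataFrame) -> np.ndarray:
    """Probability of deterioration within the horizon for each sample."""
    if model.estimator is None:
        raise RegistryMismatchError("model is not fitted")
    if list(X.columns) != model.feature_names:
        unseen = [c for c in X.columns if c not in (model.feature_names or [])]
        lost = [c for c in (model.feature_names or []) if c not in X.columns]
        raise RegistryMismatchError(
            f"feature registry mismatch: unseen columns {unseen}, missing columns {lost}")
    if len(X) == 0:
        return np.empty(0)
    return model.estimator.predict_proba(X.to_numpy(float))[:, 1]
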