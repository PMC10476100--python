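"""Six-stage ripeness classification with classical classifiers.

Four classifier families are supported — logistic regression (LR),
k-nearest neighbors (KNN), random forest (RF) and a support-vector machine
(SVM) — each with published default hyperparameters tuned for regional
color features on the 0-255 scale (no feature standardization is applied:
the SVM's default ``gamma=5e-4`` is calibrated for unscaled 8-bit means,
and rescaling would invalidate it).

Hyperparameter tuning uses stratified 5-fold cross-validation over a grid,
selecting the highest mean accuracy and breaking ties toward the simpler
model (fewer neighbors/trees, smaller C).

Evaluation reports accuracy, the 6×6 confusion matrix (rows = true), and
one-vs-rest precision / recall / F1 per class:

    P = TP / (TP + FP),  R = TP / (TP + FN),  F1 = 2PR / (P + R),
    accuracy = trace(confusion) / total.
"""

from __future__ import annotations

import json
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import sklearn
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as sk_confusion_matrix
from sklearn.model_selection import ParameterGrid, StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .colors import FeatureVector
from .errors import SchemaMismatch, TooFewSamples

@contextmanager
def _quiet_fit():
    """Suppress scikit-learn's pending rename of SVC's ``probability`` flag.

    ``probability=True`` *is* the documented probability model here
    (pairwise-coupled Platt sigmoids fitted within training).
    """
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore",
            message=r"The `probability` parameter was deprecated",
            category=FutureWarning,
        )
        yield

#: Ordinal ripeness stages, index = integer label.
STAGE_NAMES = ("White", "Breaking", "Turning-1", "Turning-2", "Ripe", "Full ripe")

#: Published default hyperparameters per family.
DEFAULT_PARAMS: dict[str, dict] = {
    "LR": {"C": 0.7, "solver": "newton-cg", "penalty": "l2"},
    "KNN": {"n_neighbors": 12},
    "RF": {"max_depth": 20, "n_estimators": 35},
    "SVM": {"C": 10, "kernel": "rbf", "gamma": 0.0005},
}

#: Default tuning grids bracketing the default optima; user-overridable.
DEFAULT_GRIDS: dict[str, dict] = {
    "LR": {"C": [0.1, 0.4, 0.7, 1.0]},
    "KNN": {"n_neighbors": list(range(4, 21))},
    "RF": {"n_estimators": [15, 25, 35, 50], "max_depth": [10, 20, 30]},
    "SVM": {"C": [0.1, 1, 10, 100], "gamma": [5e-5, 5e-4, 5e-3]},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus hyperparameters and an optional tuning grid."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    tuning_grid: dict | None = None

    def __post_init__(self):
        if self.family not in DEFAULT_PARAMS:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {list(DEFAULT_PARAMS)}"
            )

    @property
    def params(self) -> dict:
        """Defaults overlaid with any user-supplied hyperparameters."""
        return {**DEFAULT_PARAMS[self.family], **self.hyperparameters}

    @property
    def grid(self) -> dict:
        return self.tuning_grid or DEFAULT_GRIDS[self.family]


def make_spec(family: str, **hyperparameters) -> ClassifierSpec:
    """Convenience constructor: family defaults overlaid with keyword overrides."""
    return ClassifierSpec(family=family, hyperparameters=hyperparameters)


def _build_estimator(spec: ClassifierSpec, seed: int):
    p = spec.params
    if spec.family == "LR":
        p = dict(p)
        # ridge (l2) is LogisticRegression's default behavior; passing the
        # name explicitly is deprecated in scikit-learn >= 1.8
        if p.get("penalty") == "l2":
            p.pop("penalty")
        return LogisticRegression(max_iter=2000, **p)
    if spec.family == "KNN":
        return KNeighborsClassifier(**p)
    if spec.family == "RF":
        return RandomForestClassifier(random_state=seed, **p)
    if spec.family == "SVM":
        return SVC(probability=True, random_state=seed, **p)
    raise AssertionError(spec.family)  # pragma: no cover


def _check_class_counts(labels: np.ndarray, min_per_class: int) -> None:
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < min_per_class:
        raise TooFewSamples(
            f"need at least {min_per_class} samples per class, "
            f"smallest class has {counts.min()}"
        )


def _complexity_key(params: dict) -> tuple:
    """Sort key ordering candidates simplest-first, for deterministic tie-breaks."""
    return tuple((k, params[k]) for k in sorted(params))


def tune(
    features: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec,
    seed: int = 0,
) -> ClassifierSpec:
    """Grid search with stratified 5-fold CV; returns the spec at the best point.

    The candidate with the highest mean CV accuracy wins; exact ties go to
    the simpler candidate (grid candidates are scanned simplest-first).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    _check_class_counts(y, 5)
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    best_score = -np.inf
    best_params: dict | None = None
    for params in sorted(ParameterGrid(spec.grid), key=_complexity_key):
        candidate = replace(spec, hyperparameters={**spec.hyperparameters, **params})
        est = _build_estimator(candidate, seed)
        with _quiet_fit():
            score = float(cross_val_score(est, X, y, cv=cv, scoring="accuracy").mean())
        if score > best_score + 1e-12:
            best_score = score
            best_params = params
    assert best_params is not None
    return replace(spec, hyperparameters={**spec.hyperparameters, **best_params})


@dataclass
class RipenessModel:
    """A fitted classifier plus the feature schema it was trained on."""

    estimator: object
    spec: ClassifierSpec
    classes: np.ndarray
    schema: list[tuple[str, str]] | None
    seed: int
    n_features: int = 0

    def _check(self, X: np.ndarray, schema=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise SchemaMismatch(
                f"model expects {self.n_features} features, got {X.shape[1]}"
            )
        if schema is not None and self.schema is not None:
            if [tuple(s) for s in schema] != [tuple(s) for s in self.schema]:
                raise SchemaMismatch("feature schema differs from training schema")
        return X

    def predict(self, X, schema=None) -> np.ndarray:
        return self.estimator.predict(self._check(X, schema))

    def predict_proba(self, X, schema=None) -> np.ndarray:
        """Per-class probabilities; rows sum to 1, columns follow ``classes``."""
        return self.estimator.predict_proba(self._check(X, schema))


def stack_features(vectors: list[FeatureVector]) -> tuple[np.ndarray, list]:
    """Stack feature vectors into a design matrix, checking schema consistency."""
    if not vectors:
        raise ValueError("no feature vectors given")
    schema = vectors[0].schema
    for v in vectors[1:]:
        if v.schema != schema:
            raise SchemaMismatch("feature vectors have inconsistent schemas")
    return np.vstack([v.values for v in vectors]), schema


def fit(
    features: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec,
    seed: int = 0,
    schema: list | None = None,
) -> RipenessModel:
    """Fit a classifier; deterministic for a fixed seed.

    Raises
    ------
    TooFewSamples
        If the training set contains fewer than two classes.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    if np.unique(y).size < 2:
        raise TooFewSamples("training set must contain at least two classes")
    est = _build_estimator(spec, seed)
    with _quiet_fit():
        est.fit(X, y)
    return RipenessModel(
        estimator=est,
        spec=spec,
        classes=est.classes_,
        schema=schema,
        seed=seed,
        n_features=X.shape[1],
    )


@dataclass
class EvalReport:
    """Accuracy, per-class one-vs-rest metrics, and the confusion matrix."""

    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    confusion: np.ndarray
    classes: np.ndarray

    def to_dict(self) -> dict:
        names = [
            STAGE_NAMES[c] if 0 <= int(c) < len(STAGE_NAMES) else str(c)
            for c in self.classes
        ]
        return {
            "accuracy": round(self.accuracy, 6),
            "classes": names,
            "precision": [round(v, 6) for v in self.precision],
            "recall": [round(v, 6) for v in self.recall],
            "f1": [round(v, 6) for v in self.f1],
            "confusion": self.confusion.tolist(),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def confusion_frame(self) -> pd.DataFrame:
        names = [
            STAGE_NAMES[c] if 0 <= int(c) < len(STAGE_NAMES) else str(c)
            for c in self.classes
        ]
        return pd.DataFrame(self.confusion, index=names, columns=names)


def evaluate(model: RipenessModel, features, labels) -> EvalReport:
    """Evaluate on labelled data: confusion matrix and one-vs-rest metrics."""
    y_true = np.asarray(labels)
    y_pred = model.predict(features)
    classes = model.classes
    cm = sk_confusion_matrix(y_true, y_pred, labels=classes)
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(
            precision + recall > 0,
            2 * precision * recall / (precision + recall),
            0.0,
        )
    accuracy = float(tp.sum() / cm.sum()) if cm.sum() else 0.0
    return EvalReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        confusion=cm,
        classes=classes,
    )


@dataclass
class RegionAblation:
    """Results of training on single sub-regions and region combinations.

    ``contributions`` counts correct test classifications per (true stage,
    region); ``accuracies`` maps a region-combination key like ``"R1"`` or
    ``"R1R2R3R4"`` to its test accuracy.
    """

    contributions: pd.DataFrame
    accuracies: dict[str, float]
    predictions: dict[str, np.ndarray]


def subregion_contribution(
    features_by_region_train: dict[str, np.ndarray],
    labels_train: np.ndarray,
    features_by_region_test: dict[str, np.ndarray],
    labels_test: np.ndarray,
    spec: ClassifierSpec,
    seed: int = 0,
    combos: list[tuple[str, ...]] | None = None,
) -> RegionAblation:
    """Train one classifier per sub-region (and per combination) and tabulate
    correct classifications per true ripeness stage.

    A region that carries no information for a stage shows a near-chance
    count there; comparing columns reveals which part of the fruit decides
    which stage.
    """
    regions = list(features_by_region_train)
    y_train = np.asarray(labels_train)
    y_test = np.asarray(labels_test)
    stages = np.unique(np.concatenate([y_train, y_test]))

    if combos is None:
        combos = [(r,) for r in regions] + [tuple(regions)]
    else:
        combos = [tuple(c) for c in combos]
        for c in combos:
            missing = set(c) - set(regions)
            if missing:
                raise KeyError(f"unknown regions in combo {c}: {missing}")

    accuracies: dict[str, float] = {}
    predictions: dict[str, np.ndarray] = {}
    counts = {}
    for combo in combos:
        key = "".join(combo)
        X_tr = np.hstack([features_by_region_train[r] for r in combo])
        X_te = np.hstack([features_by_region_test[r] for r in combo])
        model = fit(X_tr, y_train, spec, seed=seed)
        pred = model.predict(X_te)
        predictions[key] = pred
        accuracies[key] = float((pred == y_test).mean())
        if len(combo) == 1:
            counts[key] = [
                int(((y_test == s) & (pred == y_test)).sum()) for s in stages
            ] + [int((pred == y_test).sum())]

    index = [
        STAGE_NAMES[s] if 0 <= int(s) < len(STAGE_NAMES) else str(s)
        for s in stages
    ] + ["Total"]
    contributions = pd.DataFrame(counts, index=index)
    return RegionAblation(
        contributions=contributions, accuracies=accuracies, predictions=predictions
    )


def save_model(model: RipenessModel, path) -> None:
    """Persist a fitted model as a joblib bundle plus a JSON metadata sidecar."""
    path = Path(path)
    bundle = {
        "estimator": model.estimator,
        "spec_family": model.spec.family,
        "spec_params": model.spec.params,
        "classes": model.classes,
        "schema": model.schema,
        "seed": model.seed,
        "n_features": model.n_features,
    }
    joblib.dump(bundle, path)
    meta = {
        "family": model.spec.family,
        "hyperparameters": {k: v for k, v in model.spec.params.items()},
        "classes": [int(c) for c in model.classes],
        "schema": [list(s) for s in model.schema] if model.schema else None,
        "seed": model.seed,
        "n_features": model.n_features,
        "sklearn_version": sklearn.__version__,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def load_model(path) -> RipenessModel:
    bundle = joblib.load(Path(path))
    spec = ClassifierSpec(
        family=bundle["spec_family"], hyperparameters=bundle["spec_params"]
    )
    return RipenessModel(
        estimator=bundle["estimator"],
        spec=spec,
        classes=bundle["classes"],
        schema=[tuple(s) for s in bundle["schema"]] if bundle["schema"] else None,
        seed=bundle["seed"],
        n_features=bundle["n_features"],
    )
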