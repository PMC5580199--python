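"""Three-class risk classifier: random forest, grid search, 10-fold CV.

The classifier maps 16-feature windows to {low, medium, high} asthma-attack
risk.  A random forest is used (bagging controls over-fitting on small
personalized datasets); evaluation is 10-fold cross-validation over a random
partition into near-equal subsamples, with hyperparameter grid search nested
inside each training fold (inner 5-fold CV) so the reported outer accuracy
stays unbiased.  A Gaussian naive Bayes baseline runs through the same
harness.  The chance level for three balanced classes is 1/3 (33.33%).

Missing feature values (NaN) are median-imputed; imputation medians are
learned from training data only and stored in the model bundle for
prediction time.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline

from .features import FEATURE_ORDER, FeatureVector
from .labels import RISK_ORDER, RiskLevel

__all__ = [
    "DEFAULT_GRID",
    "CVResult",
    "ModelBundle",
    "chance_level",
    "crossvalidate",
    "train",
    "predict",
]

#: Default random-forest hyperparameter grid: small, standard, desk-scale.
DEFAULT_GRID: dict[str, list] = {
    "model__n_estimators": [100, 300],
    "model__max_depth": [None, 5, 10],
    "model__max_features": ["sqrt", None],
}

_CLASS_NAMES = tuple(level.value for level in RISK_ORDER)


def chance_level(n_classes: int) -> float:
    """Expected accuracy of a uniform random predictor: 1 / n_classes."""
    if n_classes < 2:
        raise ValueError(f"need at least two classes, got {n_classes}")
    return 1.0 / n_classes


def _as_matrix(X) -> np.ndarray:
    """Coerce features to an (n, 16) float array in FEATURE_ORDER."""
    if isinstance(X, pd.DataFrame):
        missing = set(FEATURE_ORDER) - set(X.columns)
        if missing:
            raise ValueError(f"feature columns missing: {sorted(missing)}")
        return X.loc[:, list(FEATURE_ORDER)].to_numpy(dtype=float)
    if len(X) and isinstance(X[0], FeatureVector):
        return np.vstack([fv.as_array() for fv in X])
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(FEATURE_ORDER):
        raise ValueError(f"expected (n, {len(FEATURE_ORDER)}) features, got {arr.shape}")
    return arr


def _as_labels(y) -> np.ndarray:
    out = np.array(
        [lbl.value if isinstance(lbl, RiskLevel) else str(lbl) for lbl in y], dtype=object
    )
    bad = set(out) - set(_CLASS_NAMES)
    if bad:
        raise ValueError(f"unknown risk labels: {sorted(bad)}")
    return out


def _make_estimator(kind: str, seed: int, params: Mapping | None = None) -> Pipeline:
    if kind == "rf":
        model = RandomForestClassifier(random_state=seed, n_jobs=1)
    elif kind == "nb":
        model = GaussianNB()
    else:
        raise ValueError(f"unknown estimator kind {kind!r}")
    pipe = Pipeline(
        [
            ("impute", SimpleImputer(strategy="median", keep_empty_features=True)),
            ("model", model),
        ]
    )
    if params:
        pipe.set_params(**params)
    return pipe


@dataclass
class CVResult:
    """Outcome of k-fold cross-validation.

    ``confusion`` rows are true classes, columns predicted, both in
    (low, medium, high) order, summed over folds; its total equals
    ``n_samples`` because every sample is validated exactly once.
    """

    fold_accuracies: list[float]
    confusion: np.ndarray
    n_samples: int
    class_counts: dict[str, int]
    best_params: list[dict] = field(default_factory=list)
    fold_indices: list[np.ndarray] = field(default_factory=list)
    fold_predictions: list[np.ndarray] = field(default_factory=list)
    seed: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))

    def summary(self) -> dict:
        return {
            "mean_accuracy": self.mean,
            "sd_accuracy": self.sd,
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "n_samples": self.n_samples,
            "class_counts": self.class_counts,
            "confusion": self.confusion.tolist(),
            "confusion_order": list(_CLASS_NAMES),
            "best_params": self.best_params,
            "seed": self.seed,
        }


def crossvalidate(
    X,
    y,
    grid: Mapping[str, list] | None = None,
    seed: int = 0,
    n_folds: int = 10,
    inner_folds: int = 5,
    estimator: str = "rf",
) -> CVResult:
    """K-fold cross-validated accuracy with nested grid search.

    Samples are randomly partitioned into ``n_folds`` subsamples whose sizes
    differ by at most one; each is validated exactly once against a model
    fit — including imputation and grid search — on the remaining folds
    only.  ``grid=None`` uses :data:`DEFAULT_GRID`; pass ``{}`` for a fixed
    default-hyperparameter fit (no inner search).  Fully reproducible from
    ``seed``.
    """
    Xm = _as_matrix(X)
    ym = _as_labels(y)
    n = Xm.shape[0]
    if n < n_folds:
        raise ValueError(f"need >= {n_folds} samples for {n_folds}-fold CV, got {n}")
    if n < 20:
        raise ValueError(f"need >= 20 labeled samples, got {n}")
    classes, counts = np.unique(ym, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation needs at least two classes present")
    if grid is None:
        grid = DEFAULT_GRID
    if estimator == "nb":
        grid = {k: v for k, v in grid.items() if not k.startswith("model__")}

    outer = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_acc: list[float] = []
    best_params: list[dict] = []
    fold_indices: list[np.ndarray] = []
    fold_predictions: list[np.ndarray] = []
    y_true_all: list[np.ndarray] = []
    y_pred_all: list[np.ndarray] = []

    for k, (tr, va) in enumerate(outer.split(Xm)):
        base = _make_estimator(estimator, seed=seed + 1)
        if grid and any(len(v) > 1 for v in grid.values()):
            inner = KFold(n_splits=inner_folds, shuffle=True, random_state=seed + 100 + k)
            search = GridSearchCV(base, dict(grid), cv=inner, scoring="accuracy", n_jobs=1)
            search.fit(Xm[tr], ym[tr])
            fitted = search.best_estimator_
            best_params.append(dict(search.best_params_))
        else:
            if grid:
                base.set_params(**{key: vals[0] for key, vals in grid.items()})
            base.fit(Xm[tr], ym[tr])
            fitted = base
            best_params.append({key: vals[0] for key, vals in grid.items()} if grid else {})
        pred = fitted.predict(Xm[va])
        fold_acc.append(float(np.mean(pred == ym[va])))
        fold_indices.append(va)
        fold_predictions.append(pred)
        y_true_all.append(ym[va])
        y_pred_all.append(pred)

    conf = confusion_matrix(
        np.concatenate(y_true_all), np.concatenate(y_pred_all), labels=list(_CLASS_NAMES)
    )
    return CVResult(
        fold_accuracies=fold_acc,
        confusion=conf,
        n_samples=n,
        class_counts={c: int(cnt) for c, cnt in zip(classes, counts)},
        best_params=best_params,
        fold_indices=fold_indices,
        fold_predictions=fold_predictions,
        seed=seed,
    )


@dataclass
class ModelBundle:
    """A fitted classifier plus everything needed to reproduce predictions.

    Holds the fitted imputer+forest pipeline, the fixed feature order, the
    training-set imputation medians, the hyperparameters used, a fingerprint
    of the training data, and the seed.  Round-trips through
    :meth:`save`/:meth:`load` with identical predictions.
    """

    pipeline: Pipeline
    feature_order: tuple[str, ...]
    imputation_medians: dict[str, float]
    hyperparameters: dict
    training_fingerprint: str
    seed: int

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @staticmethod
    def load(path: str | Path) -> "ModelBundle":
        bundle = joblib.load(Path(path))
        if not isinstance(bundle, ModelBundle):
            raise TypeError(f"{path} does not contain a ModelBundle")
        return bundle


def _fingerprint(Xm: np.ndarray, ym: np.ndarray, seed: int) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(Xm).tobytes())
    h.update("|".join(map(str, ym)).encode())
    h.update(str(seed).encode())
    return h.hexdigest()


def train(
    X,
    y,
    hyperparameters: Mapping | None = None,
    seed: int = 0,
    estimator: str = "rf",
) -> ModelBundle:
    """Fit a final model on all labeled samples and bundle it.

    ``hyperparameters`` uses pipeline parameter names (e.g.
    ``model__n_estimators``); defaults are scikit-learn's.  Refitting with
    the same data and seed is prediction-identical.
    """
    Xm = _as_matrix(X)
    ym = _as_labels(y)
    if Xm.shape[0] < 20:
        raise ValueError(f"need >= 20 labeled samples, got {Xm.shape[0]}")
    if len(np.unique(ym)) < 2:
        raise ValueError("training needs at least two classes present")
    pipe = _make_estimator(estimator, seed=seed, params=hyperparameters)
    pipe.fit(Xm, ym)
    medians = {
        name: float(v)
        for name, v in zip(FEATURE_ORDER, pipe.named_steps["impute"].statistics_)
    }
    return ModelBundle(
        pipeline=pipe,
        feature_order=FEATURE_ORDER,
        imputation_medians=medians,
        hyperparameters=dict(hyperparameters or {}),
        training_fingerprint=_fingerprint(Xm, ym, seed),
        seed=seed,
    )


def predict(
    bundle: ModelBundle, fv: FeatureVector | Sequence[float] | np.ndarray
) -> tuple[RiskLevel, dict[str, float]]:
    """Predict one window's risk level and class probabilities.

    Missing (NaN) features are imputed with the bundle's stored training
    medians.  The label is the argmax class; exact probability ties break
    deterministically toward the higher risk level (safety-first).
    """
    if bundle.feature_order != FEATURE_ORDER:
        raise ValueError("model bundle feature order does not match FeatureVector order")
    if isinstance(fv, FeatureVector):
        row = fv.as_array()
    else:
        row = np.asarray(fv, dtype=float)
        if row.shape != (len(FEATURE_ORDER),):
            raise ValueError(
                f"expected {len(FEATURE_ORDER)} features in declared order, got {row.shape}"
            )
    proba = bundle.pipeline.predict_proba(row.reshape(1, -1))[0]
    model_classes = list(bundle.pipeline.named_steps["model"].classes_)
    probs = {name: float(proba[model_classes.index(name)]) if name in model_classes else 0.0
             for name in _CLASS_NAMES}
    best = max(RISK_ORDER, key=lambda lvl: (probs[lvl.value], lvl.rank))
    return best, probs
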