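"""Tuned random-forest and SVM peptide classifiers.

Hyperparameters are selected by stratified k-fold grid search on accuracy and
the winning configuration is refit on the full training set:

* RF — number of trees in {100, 200, 300, 400, 500} and number of candidate
  features per split (mtry) in 1..10 (clipped to the feature count);
* SVM — RBF kernel with regularization C in {0.25, 0.5, 1, 2, 4}; the kernel
  width is fixed by the median-pairwise-distance heuristic on the
  (standardized) training data, gamma = 1/(2·median²).

Features are standardized with train-set mean/SD before the SVM and left raw
for the RF; the scaling is frozen into the fitted model.  The positive class
is ACP throughout, scores are P(ACP) and labels are scores thresholded at
0.5.  All randomness (fold assignment, bootstraps, Platt calibration) derives
from ``random_state``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .sequence_io import ACP, NON_ACP

_SCHEMA_VERSION = 1

RF_NTREE_GRID = (100, 200, 300, 400, 500)
RF_MTRY_GRID = tuple(range(1, 11))
SVM_C_GRID = (0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass
class ModelSpec:
    """Algorithm choice plus the hyperparameter search space."""

    algorithm: str = "SVM"
    rf_ntree_grid: tuple[int, ...] = RF_NTREE_GRID
    rf_mtry_grid: tuple[int, ...] = RF_MTRY_GRID
    svm_c_grid: tuple[float, ...] = SVM_C_GRID
    tuning_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ("RF", "SVM"):
            raise ValueError(f"algorithm must be 'RF' or 'SVM', got {self.algorithm!r}")
        if self.tuning_folds < 2:
            raise ValueError("tuning_folds must be >= 2")
        if not (self.rf_ntree_grid and self.rf_mtry_grid and self.svm_c_grid):
            raise ValueError("hyperparameter grids must be non-empty")


def _median_gamma(X: np.ndarray) -> float:
    """RBF width from the median pairwise Euclidean distance, gamma = 1/(2 m^2)."""
    n = len(X)
    if n > 500:  # subsample for the heuristic only; deterministic
        idx = np.linspace(0, n - 1, 500).astype(int)
        X = X[idx]
    med = np.median(pdist(X))
    if med == 0:
        return 1.0 / X.shape[1]
    return 1.0 / (2.0 * med * med)


class PeptideClassifier(BaseEstimator, ClassifierMixin):
    """Grid-search-tuned RF or SVM classifier for peptide feature matrices.

    ``fit`` accepts a feature matrix (DataFrame preferred: column names are
    recorded and enforced at prediction time) and string labels with ACP as
    the positive class.  After fitting, ``best_params_`` holds the selected
    hyperparameters and ``cv_accuracy_`` the inner-CV accuracy of the winner.
    """

    def __init__(
        self,
        algorithm: str = "SVM",
        rf_ntree_grid: tuple[int, ...] = RF_NTREE_GRID,
        rf_mtry_grid: tuple[int, ...] = RF_MTRY_GRID,
        svm_c_grid: tuple[float, ...] = SVM_C_GRID,
        tuning_folds: int = 5,
        random_state: int = 0,
    ):
        self.algorithm = algorithm
        self.rf_ntree_grid = rf_ntree_grid
        self.rf_mtry_grid = rf_mtry_grid
        self.svm_c_grid = svm_c_grid
        self.tuning_folds = tuning_folds
        self.random_state = random_state

    @classmethod
    def from_spec(cls, spec: ModelSpec) -> "PeptideClassifier":
        return cls(
            algorithm=spec.algorithm,
            rf_ntree_grid=spec.rf_ntree_grid,
            rf_mtry_grid=spec.rf_mtry_grid,
            svm_c_grid=spec.svm_c_grid,
            tuning_folds=spec.tuning_folds,
            random_state=spec.seed,
        )

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        values, names = _matrix(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data contains a single class")
        counts = {c: int((y == c).sum()) for c in classes}
        if min(counts.values()) < self.tuning_folds:
            raise ValueError(
                f"each class needs >= tuning_folds={self.tuning_folds} samples, "
                f"got {counts}"
            )
        self.feature_names_ = names
        self.classes_ = classes
        self.positive_label_ = ACP if ACP in classes else classes[-1]

        cv = StratifiedKFold(
            n_splits=self.tuning_folds, shuffle=True, random_state=self.random_state
        )
        if self.algorithm == "RF":
            self.scaler_mean_ = None
            self.scaler_sd_ = None
            mtry = sorted({min(m, values.shape[1]) for m in self.rf_mtry_grid})
            grid = {
                "n_estimators": list(self.rf_ntree_grid),
                "max_features": mtry,
            }
            search = GridSearchCV(
                RandomForestClassifier(random_state=self.random_state),
                grid,
                scoring="accuracy",
                cv=cv,
                n_jobs=None,
            )
            search.fit(values, y)
            self.best_params_ = dict(search.best_params_)
            self.cv_accuracy_ = float(search.best_score_)
            self.model_ = search.best_estimator_
        elif self.algorithm == "SVM":
            mean = values.mean(axis=0)
            sd = values.std(axis=0)
            sd[sd == 0] = 1.0
            self.scaler_mean_ = mean
            self.scaler_sd_ = sd
            Xs = (values - mean) / sd
            gamma = _median_gamma(Xs)
            search = GridSearchCV(
                SVC(kernel="rbf", gamma=gamma),
                {"C": list(self.svm_c_grid)},
                scoring="accuracy",
                cv=cv,
                n_jobs=None,
            )
            search.fit(Xs, y)
            self.best_params_ = {"C": float(search.best_params_["C"]), "gamma": gamma}
            self.cv_accuracy_ = float(search.best_score_)
            with warnings.catch_warnings():
                # sklearn 1.9 deprecates the probability flag; Platt scaling
                # on the training data is exactly the calibration we want
                warnings.simplefilter("ignore", FutureWarning)
                self.model_ = SVC(
                    kernel="rbf",
                    C=self.best_params_["C"],
                    gamma=gamma,
                    probability=True,
                    random_state=self.random_state,
                )
                self.model_.fit(Xs, y)
        else:
            raise ValueError(f"algorithm must be 'RF' or 'SVM', got {self.algorithm!r}")
        return self

    # ------------------------------------------------------ predict/scores
    def _prepare(self, X) -> np.ndarray:
        values, names = _matrix(X)
        if names is not None and self.feature_names_ is not None:
            if list(names) != list(self.feature_names_):
                missing = sorted(set(self.feature_names_) - set(names))
                extra = sorted(set(names) - set(self.feature_names_))
                if missing or extra:
                    raise ValueError(
                        f"feature columns mismatch: missing {missing}, extra {extra}"
                    )
                values = pd.DataFrame(values, columns=list(names))[
                    list(self.feature_names_)
                ].to_numpy()
        if self.scaler_mean_ is not None:
            values = (values - self.scaler_mean_) / self.scaler_sd_
        return values

    def predict_scores(self, X) -> np.ndarray:
        """P(ACP) per row: RF vote fraction / calibrated SVM probability."""
        if len(X) == 0:
            return np.empty(0)
        values = self._prepare(X)
        proba = self.model_.predict_proba(values)
        pos_col = list(self.model_.classes_).index(self.positive_label_)
        return proba[:, pos_col]

    def predict_proba(self, X) -> np.ndarray:
        if len(X) == 0:
            return np.empty((0, len(self.classes_)))
        return self.model_.predict_proba(self._prepare(X))

    def predict(self, X) -> np.ndarray:
        """Labels from scores thresholded at 0.5 (positive class ACP)."""
        scores = self.predict_scores(X)
        negative = next(c for c in self.classes_ if c != self.positive_label_)
        return np.where(scores > 0.5, self.positive_label_, negative)

    # -------------------------------------------------------- persistence
    def save(self, path) -> None:
        """Persist the fitted model to a single-file artifact."""
        payload = {
            "schema_version": _SCHEMA_VERSION,
            "params": self.get_params(),
            "state": {
                k: getattr(self, k)
                for k in (
                    "feature_names_",
                    "classes_",
                    "positive_label_",
                    "best_params_",
                    "cv_accuracy_",
                    "scaler_mean_",
                    "scaler_sd_",
                    "model_",
                )
            },
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path) -> "PeptideClassifier":
        payload = joblib.load(path)
        version = payload.get("schema_version")
        if version != _SCHEMA_VERSION:
            raise ValueError(
                f"model artifact schema version {version!r} is not supported "
                f"(expected {_SCHEMA_VERSION})"
            )
        obj = cls(**payload["params"])
        for k, v in payload["state"].items():
            setattr(obj, k, v)
        return obj


def _matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


def tune_and_train(X, y, spec: ModelSpec | None = None) -> PeptideClassifier:
    """Grid-search hyperparameters by stratified CV and refit on all data."""
    spec = spec or ModelSpec()
    return PeptideClassifier.from_spec(spec).fit(X, y)


def predict_labels(model: PeptideClassifier, X) -> np.ndarray:
    return model.predict(X)


def predict_scores(model: PeptideClassifier, X) -> np.ndarray:
    return model.predict_scores(X)
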