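"""The three classifier configurations with calibrated class posteriors.

* ``svm_rbf_ovr`` — one-vs-rest support vector machines with an RBF kernel;
  per-class Platt-scaled posteriors, renormalised across classes.
* ``random_forest`` — bagged decision trees (default 100); the posterior is
  the tree-vote fraction.
* ``neural_net`` — a single hidden layer of 7 units with a 3-unit softmax
  output, trained for at most 250 epochs.

All models consume the same (n_trials, n_features) matrix of selected,
z-scored features. Training rows are canonically ordered before fitting so
predictions are invariant to the order records arrive in.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .dataio import IntensityClass
from .errors import ConfigError, ContractError, DataError

__all__ = ["ClassifierSpec", "TrainedModel", "train", "CLASSIFIER_KINDS"]

CLASSIFIER_KINDS = ("svm_rbf_ovr", "random_forest", "neural_net")
CLASS_ORDER = (IntensityClass.LOW, IntensityClass.MODERATE, IntensityClass.HIGH)


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameters of one classifier configuration."""

    kind: str
    n_trees: int = 100  # random forest
    hidden_units: int = 7  # neural net
    max_epochs: int = 250
    learning_rate: float = 0.01
    svm_c: float = 1.0
    svm_gamma: float | str = "auto"  # "auto" = 1 / n_features
    rng_seed: int = 0

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise ConfigError("kind", f"unknown classifier kind {self.kind!r}")
        if self.kind == "random_forest" and self.n_trees not in (50, 100, 150):
            raise ConfigError("n_trees", f"n_trees must be one of 50/100/150, got {self.n_trees}")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate", "learning rate must be positive")


def _build_estimator(spec: ClassifierSpec):
    if spec.kind == "svm_rbf_ovr":
        # one-vs-rest binary RBF SVMs, each with a Platt-scaled (sigmoid)
        # posterior fitted by internal cross-validation
        return OneVsRestClassifier(
            CalibratedClassifierCV(
                SVC(
                    kernel="rbf",
                    C=spec.svm_c,
                    gamma=spec.svm_gamma,
                    random_state=spec.rng_seed,
                ),
                method="sigmoid",
                ensemble=False,
            )
        )
    if spec.kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=spec.n_trees, random_state=spec.rng_seed
        )
    return MLPClassifier(
        hidden_layer_sizes=(spec.hidden_units,),
        max_iter=spec.max_epochs,
        learning_rate_init=spec.learning_rate,
        random_state=spec.rng_seed,
    )


@dataclass
class TrainedModel:
    """A fitted classifier plus the contract needed to apply it safely."""

    spec: ClassifierSpec
    estimator: object
    feature_names: list
    class_order: tuple = CLASS_ORDER

    def predict_posterior(self, X: pd.DataFrame) -> np.ndarray:
        """Row-stochastic (n, 3) posterior matrix in class order low,
        moderate, high."""
        if list(X.columns) != self.feature_names:
            raise ContractError(
                "feature columns at predict time do not match training features"
            )
        proba = self.estimator.predict_proba(X.to_numpy(dtype=float))
        full = np.zeros((len(X), len(self.class_order)))
        for j, cls in enumerate(self.estimator.classes_):
            full[:, int(cls)] = proba[:, j]
        row_sums = full.sum(axis=1, keepdims=True)
        row_sums[row_sums == 0] = 1.0
        return full / row_sums

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Hard labels; posterior ties break toward the higher intensity."""
        return argmax_high(self.predict_posterior(X))

    def save(self, path) -> None:
        """Versioned binary blob + JSON sidecar (spec, classes, features)."""
        path = Path(path)
        joblib.dump({"version": 1, "estimator": self.estimator}, path)
        sidecar = {
            "version": 1,
            "spec": self.spec.__dict__,
            "class_order": [c.label for c in self.class_order],
            "feature_names": self.feature_names,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "TrainedModel":
        path = Path(path)
        blob = joblib.load(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            spec=ClassifierSpec(**sidecar["spec"]),
            estimator=blob["estimator"],
            feature_names=sidecar["feature_names"],
        )


def argmax_high(posteriors: np.ndarray) -> np.ndarray:
    """Per-row argmax over class scores, ties resolved toward the higher
    intensity class (conservative for safety-monitoring use)."""
    posteriors = np.asarray(posteriors, dtype=float)
    n_classes = posteriors.shape[-1]
    rev = posteriors[..., ::-1]
    return (n_classes - 1) - np.argmax(rev, axis=-1)


def train(spec: ClassifierSpec, X: pd.DataFrame, y: np.ndarray) -> TrainedModel:
    """Fit one classifier. ``y`` holds IntensityClass codes (0/1/2)."""
    y = np.asarray(y, dtype=int)
    if X.isna().to_numpy().any():
        raise DataError("feature matrix contains missing values; impute first")
    if len(np.unique(y)) < 2:
        raise DataError("training labels contain a single class")
    est = _build_estimator(spec)
    # canonical row order: predictions must not depend on how the caller
    # happened to order the training rows
    arr = X.to_numpy(dtype=float)
    order = np.lexsort(tuple(arr[:, j] for j in reversed(range(arr.shape[1]))))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(arr[order], y[order])
    return TrainedModel(spec=spec, estimator=est, feature_names=list(X.columns))
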