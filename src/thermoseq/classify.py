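"""Classifiers for the fused feature space.

The primary model is a single-hidden-layer perceptron (input → 100 ReLU units
→ 1 logistic unit) trained by mini-batch SGD with Nesterov momentum 0.8,
batch size 60, learning rate 0.001 and 1200 epochs on binary cross-entropy.
Three baselines with fixed hyperparameters accompany it: an RBF-kernel SVM
(γ = 1e-4, C = 900), a random forest (500 trees, max depth 100, min split 10)
and k-nearest-neighbours (k = 6, Minkowski power 1, leaf size 2).

Distance- and gradient-based models (MLP, SVM, KNN) see z-scored inputs
(scaler fitted on training rows only); the forest consumes raw features.
Fitted models carry a feature-name contract and refuse matrices whose columns
differ in name or order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass
class MLPConfig:
    """Hyperparameters of the perceptron."""

    hidden_units: int = 100
    batch_size: int = 60
    epochs: int = 1200
    learning_rate: float = 0.001
    momentum: float = 0.8
    decay: float = 1e-8  # applied as an (inert) L2 penalty
    nesterov: bool = True

    def __post_init__(self):
        if min(self.hidden_units, self.batch_size, self.epochs) <= 0:
            raise ValueError("counts must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")


@dataclass
class BaselineConfig:
    """Fixed hyperparameters of the three baseline classifiers."""

    svm_gamma: float = 1e-4
    svm_c: float = 900.0
    rf_trees: int = 500
    rf_max_depth: int = 100
    rf_min_split: int = 10
    knn_neighbors: int = 6
    knn_power: int = 1
    knn_leaf_size: int = 2

    def __post_init__(self):
        if any(v <= 0 for v in asdict(self).values()):
            raise ValueError("all baseline hyperparameters must be positive")


CLASSIFIER_KINDS = ("mlp", "svm", "rf", "knn")


class ThermophilicityClassifier(ClassifierMixin, BaseEstimator):
    """Binary protein classifier with standardisation and a column contract.

    Parameters
    ----------
    kind:
        ``mlp`` (default), ``svm``, ``rf`` or ``knn``.
    epochs:
        Training epochs for the MLP (ignored otherwise); the default follows
        the fixed-epoch schedule, reducible for cheap runs.
    random_state:
        Seeds weight initialisation and batch shuffling; with identical data
        and configuration the fitted model is identical.
    """

    def __init__(
        self,
        kind: str = "mlp",
        epochs: int = 1200,
        random_state: int = 0,
        mlp_config: MLPConfig | None = None,
        baseline_config: BaselineConfig | None = None,
    ):
        self.kind = kind
        self.epochs = epochs
        self.random_state = random_state
        self.mlp_config = mlp_config
        self.baseline_config = baseline_config

    def _build(self, n_samples: int):
        kind = self.kind
        if kind == "mlp":
            cfg = self.mlp_config or MLPConfig(epochs=self.epochs)
            return MLPClassifier(
                hidden_layer_sizes=(cfg.hidden_units,),
                activation="relu",
                solver="sgd",
                alpha=cfg.decay,
                batch_size=min(cfg.batch_size, n_samples),
                learning_rate="constant",
                learning_rate_init=cfg.learning_rate,
                momentum=cfg.momentum,
                nesterovs_momentum=cfg.nesterov,
                max_iter=cfg.epochs,
                n_iter_no_change=cfg.epochs,
                tol=0.0,
                shuffle=True,
                random_state=self.random_state,
            )
        cfg = self.baseline_config or BaselineConfig()
        if kind == "svm":
            return SVC(
                kernel="rbf",
                gamma=cfg.svm_gamma,
                C=cfg.svm_c,
                probability=True,
                random_state=self.random_state,
            )
        if kind == "rf":
            return RandomForestClassifier(
                n_estimators=cfg.rf_trees,
                max_depth=cfg.rf_max_depth,
                min_samples_split=cfg.rf_min_split,
                random_state=self.random_state,
            )
        if kind == "knn":
            return KNeighborsClassifier(
                n_neighbors=cfg.knn_neighbors,
                p=cfg.knn_power,
                leaf_size=cfg.knn_leaf_size,
            )
        raise ValueError(f"unknown classifier kind {self.kind!r}")

    def fit(self, X, y):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        Xv = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training set contains a single class")
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 training samples")
        self.classes_ = classes
        self.feature_names_ = names
        self.n_features_in_ = Xv.shape[1]
        if self.kind == "rf":
            self.scaler_ = None
        else:
            self.scaler_ = StandardScaler().fit(Xv)
            Xv = self.scaler_.transform(Xv)
        self.model_ = self._build(Xv.shape[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            warnings.simplefilter("ignore", FutureWarning)
            self.model_.fit(Xv, y)
        return self

    def _prepare(self, X) -> np.ndarray:
        if self.feature_names_ is not None:
            if not isinstance(X, pd.DataFrame):
                raise ValueError(
                    "model was fitted with named features; pass a DataFrame"
                )
            if list(X.columns) != self.feature_names_:
                missing = [c for c in self.feature_names_ if c not in X.columns]
                extra = [c for c in X.columns if c not in self.feature_names_]
                raise ValueError(
                    "feature contract violated: columns must match training "
                    f"names and order (missing={missing[:5]}, unexpected={extra[:5]})"
                )
        Xv = np.asarray(X, dtype=float)
        if Xv.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {Xv.shape[1]}"
            )
        if self.scaler_ is not None:
            Xv = self.scaler_.transform(Xv)
        return Xv

    def predict_proba(self, X) -> np.ndarray:
        """Per-sample probability of each class, columns ordered [0, 1]."""
        return self.model_.predict_proba(self._prepare(X))

    def predict_score(self, X) -> np.ndarray:
        """Probability of the thermophilic class (label 1), in [0, 1]."""
        return self.predict_proba(X)[:, list(self.classes_).index(1)]

    def predict(self, X) -> np.ndarray:
        """Hard labels at the 0.5 score threshold."""
        return (self.predict_score(X) >= 0.5).astype(int)


def standardize_fit_apply(train: pd.DataFrame, test: pd.DataFrame):
    """Z-score both matrices with statistics fitted on the training rows only.

    Constant training columns map to zeros (no division by zero).  Applying
    the returned scaler again re-standardises — the transform is not
    idempotent on already-scaled data with non-trivial statistics.
    """
    if list(train.columns) != list(test.columns):
        raise ValueError("train/test column names differ")
    scaler = StandardScaler().fit(train.to_numpy(dtype=float))
    t = pd.DataFrame(
        scaler.transform(train.to_numpy(dtype=float)),
        index=train.index, columns=train.columns,
    )
    s = pd.DataFrame(
        scaler.transform(test.to_numpy(dtype=float)),
        index=test.index, columns=test.columns,
    )
    return t, s, scaler


def train_mlp(X, y, epochs: int = 1200, random_state: int = 0, **kwargs) -> ThermophilicityClassifier:
    """Fit the perceptron on a feature matrix (thin wrapper)."""
    return ThermophilicityClassifier(
        kind="mlp", epochs=epochs, random_state=random_state, **kwargs
    ).fit(X, y)


def train_baseline(kind: str, X, y, random_state: int = 0, **kwargs) -> ThermophilicityClassifier:
    """Fit one of the baseline classifiers (svm / rf / knn)."""
    if kind not in ("svm", "rf", "knn"):
        raise ValueError(f"baseline kind must be svm, rf or knn, got {kind!r}")
    return ThermophilicityClassifier(kind=kind, random_state=random_state, **kwargs).fit(X, y)


def predict_proba(model: ThermophilicityClassifier, X) -> np.ndarray:
    """Thermophilic-class score in [0, 1] for each row of ``X``."""
    return model.predict_score(X)


def save_model(model, directory, extra_manifest: dict | None = None) -> None:
    """Persist a fitted model (or pipeline) plus a stable JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, directory / "model.joblib")
    manifest = {
        "format_version": 1,
        "model_class": type(model).__name__,
        "params": {k: repr(v) for k, v in sorted(model.get_params(deep=False).items())},
    }
    names = getattr(model, "feature_names_", None)
    if names is not None:
        manifest["feature_contract"] = list(names)
    if extra_manifest:
        manifest.update(extra_manifest)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def load_model(directory):
    """Load a model persisted by :func:`save_model`."""
    return joblib.load(Path(directory) / "model.joblib")
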