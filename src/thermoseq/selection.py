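"""ANOVA-F feature ranking, sequential backward selection, and fusion.

Features are ranked by the classical one-way ANOVA F statistic between the
two classes (between-group over within-group variance, df_b = K−1 = 1,
df_w = N−K).  Starting from the full ranked set, backward selection
repeatedly drops the lowest-ranked features and scores each intermediate
subset by cross-validated AUC of a configurable classifier; the subset with
the highest criterion wins, ties going to the smaller subset.  The chosen
per-descriptor subsets are fused by column concatenation in a fixed
descriptor order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler


@dataclass
class AnovaResult:
    """Per-feature one-way ANOVA decomposition for a two-group matrix."""

    feature_names: list[str]
    f_values: np.ndarray
    s2_between: np.ndarray
    s2_within: np.ndarray
    df_between: int
    df_within: int


def _check_Xy(X, y):
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"f{i}" for i in range(np.asarray(X).shape[1])
    ]
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if Xv.ndim != 2 or Xv.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one label per row")
    if np.isnan(Xv).any():
        raise ValueError("feature matrix contains missing values")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return Xv, y, names


def anova_f(X, y) -> AnovaResult:
    """Two-group one-way ANOVA F per feature.

    F = s²_between / s²_within with df_b = 1, df_w = N−2.  A feature with no
    within-group variance gets F = inf when the group means differ and F = 0
    when they coincide; a feature with equal group means gets F = 0.
    """
    Xv, y, names = _check_Xy(X, y)
    groups = [Xv[y == 0], Xv[y == 1]]
    if any(g.shape[0] < 2 for g in groups):
        raise ValueError("each class needs at least 2 samples for ANOVA")
    n = Xv.shape[0]
    k = 2
    grand = Xv.mean(axis=0)
    ss_between = sum(g.shape[0] * (g.mean(axis=0) - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean(axis=0)) ** 2).sum(axis=0) for g in groups)
    df_b, df_w = k - 1, n - k
    s2b = ss_between / df_b
    s2w = ss_within / df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(
            s2w > 0, s2b / np.where(s2w > 0, s2w, 1.0),
            np.where(s2b > 0, np.inf, 0.0),
        )
    return AnovaResult(names, f, s2b, s2w, df_b, df_w)


def rank_features(anova: AnovaResult) -> list[str]:
    """Feature names in descending F order; ties keep original column order."""
    order = np.argsort(-anova.f_values, kind="stable")
    return [anova.feature_names[i] for i in order]


@dataclass
class SelectionResult:
    """Audit record of one backward-selection run."""

    descriptor: str
    ranking: list[str]
    f_values: dict[str, float]
    trace: list[tuple[int, float]]  # (subset size, criterion)
    chosen: list[str]
    criterion: str = "cv_auc"

    def to_json(self, path) -> None:
        payload = {
            "descriptor": self.descriptor,
            "criterion": self.criterion,
            "ranking": self.ranking,
            "f_values": self.f_values,
            "trace": [[int(s), float(v)] for s, v in self.trace],
            "chosen": self.chosen,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SelectionResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            descriptor=d["descriptor"],
            ranking=d["ranking"],
            f_values=d["f_values"],
            trace=[(int(s), float(v)) for s, v in d["trace"]],
            chosen=d["chosen"],
            criterion=d["criterion"],
        )


def make_cv_auc_evaluator(
    classifier: str = "logreg",
    folds: int = 5,
    epochs: int = 150,
    random_state: int = 0,
) -> Callable[[np.ndarray, np.ndarray], float]:
    """Stratified k-fold cross-validated AUC of a cheap inner classifier.

    ``classifier``: ``logreg`` (fast default) or ``mlp`` (the pipeline's own
    classifier family at reduced epochs).
    """
    if classifier == "logreg":
        clf = LogisticRegression(max_iter=1000)
    elif classifier == "mlp":
        clf = MLPClassifier(
            hidden_layer_sizes=(100,),
            activation="relu",
            solver="sgd",
            learning_rate_init=0.001,
            momentum=0.8,
            nesterovs_momentum=True,
            batch_size=60,
            max_iter=epochs,
            random_state=random_state,
        )
    else:
        raise ValueError(f"unknown selection classifier {classifier!r}")
    est = make_pipeline(StandardScaler(), clf)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)

    def evaluate(X: np.ndarray, y: np.ndarray) -> float:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(cross_val_score(est, X, y, cv=cv, scoring="roc_auc").mean())

    return evaluate


class SequentialBackwardSelector(SelectorMixin, BaseEstimator):
    """Backward elimination along an ANOVA-F ranking.

    Parameters
    ----------
    step:
        Features removed per elimination round; a float < 1 is a fraction of
        the total feature count (minimum 1 per round).
    min_size:
        Smallest subset evaluated.
    evaluator:
        Callable ``(X_subset, y) -> criterion``; ``None`` builds a stratified
        CV-AUC evaluator from ``classifier``/``folds``/``epochs``.
    random_state:
        Seeds the CV folds (and the inner MLP when used); a fixed seed makes
        the whole trace reproducible.

    Attributes (after fit)
    ----------------------
    ranking_ : feature names in descending F order.
    trace_ : list of (subset size, criterion value), largest subset first.
    chosen_ : names of the winning subset (criterion-maximal; ties -> smaller).
    support_ : boolean column mask of the winning subset.
    """

    def __init__(
        self,
        step: float = 0.05,
        min_size: int = 1,
        evaluator: Callable | None = None,
        classifier: str = "logreg",
        folds: int = 5,
        epochs: int = 150,
        random_state: int = 0,
    ):
        self.step = step
        self.min_size = min_size
        self.evaluator = evaluator
        self.classifier = classifier
        self.folds = folds
        self.epochs = epochs
        self.random_state = random_state

    def fit(self, X, y):
        Xv, y, names = _check_Xy(X, y)
        n_features = Xv.shape[1]
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        anova = anova_f(Xv, y)
        anova.feature_names = names
        rank_idx = np.argsort(-anova.f_values, kind="stable").tolist()
        ranking = [names[i] for i in rank_idx]

        evaluator = self.evaluator or make_cv_auc_evaluator(
            self.classifier, self.folds, self.epochs, self.random_state
        )
        step = self.step
        if 0 < step < 1:
            step = max(1, round(step * n_features))
        step = int(step)
        if step < 1:
            raise ValueError("step must resolve to >= 1 feature per round")

        trace: list[tuple[int, float]] = []
        sizes = []
        size = n_features
        while size > self.min_size:
            sizes.append(size)
            size -= step
        sizes.append(min(self.min_size, n_features))
        sizes = sorted(set(sizes), reverse=True)

        for s in sizes:
            subset = rank_idx[:s]
            try:
                score = float(evaluator(Xv[:, subset], y))
            except Exception as exc:  # pragma: no cover - evaluator contract
                raise RuntimeError(f"criterion evaluation failed at subset size {s}") from exc
            trace.append((s, score))

        # max criterion; exact ties resolved toward the smaller subset
        best_size, best_score = trace[0]
        for s, v in trace[1:]:
            if v > best_score or (v == best_score and s < best_size):
                best_size, best_score = s, v
        chosen_idx = sorted(rank_idx[:best_size])

        self.n_features_in_ = n_features
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.anova_ = anova
        self.ranking_ = ranking
        self.trace_ = trace
        self.chosen_ = [names[i] for i in chosen_idx]
        self.support_ = np.zeros(n_features, dtype=bool)
        self.support_[chosen_idx] = True
        return self

    def _get_support_mask(self):
        return self.support_

    def result(self, descriptor: str = "") -> SelectionResult:
        f_map = {
            n: float(f) for n, f in zip(self.anova_.feature_names, self.anova_.f_values)
        }
        return SelectionResult(
            descriptor=descriptor,
            ranking=list(self.ranking_),
            f_values=f_map,
            trace=list(self.trace_),
            chosen=list(self.chosen_),
        )


def sequential_backward_select(
    X, y, descriptor: str = "", **kwargs
) -> SelectionResult:
    """Functional wrapper: run backward selection and return its audit record."""
    sel = SequentialBackwardSelector(**kwargs).fit(X, y)
    return sel.result(descriptor)


def fuse(
    matrices: Mapping[str, pd.DataFrame],
    order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Concatenate per-descriptor (already subset) matrices column-wise.

    All matrices must share identical row ids in identical order; columns are
    joined in the given descriptor order (default: the order of ``matrices``).
    Column names are expected to carry their descriptor prefix, which keeps
    every fused column traceable to exactly one (descriptor, feature) pair.
    """
    if not matrices:
        raise ValueError("nothing to fuse")
    order = list(order) if order is not None else list(matrices)
    frames = []
    ref_index = None
    for name in order:
        if name not in matrices:
            continue
        df = matrices[name]
        if ref_index is None:
            ref_index = df.index
        elif not df.index.equals(ref_index):
            raise ValueError(f"sample ids of descriptor {name!r} do not align")
        frames.append(df)
    fused = pd.concat(frames, axis=1)
    if fused.columns.duplicated().any():
        raise ValueError("fused matrix has colliding column names")
    return fused
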