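"""Evaluation metrics and permutation feature importance.

Sensitivity, specificity, accuracy and Matthews correlation coefficient are
computed literally from the confusion counts; AUC uses the rank
(Mann–Whitney) formulation — the probability that a random positive outscores
a random negative, ties counted 1/2 — which coincides with trapezoidal ROC
integration on finite samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float | None = None

    def as_dict(self) -> dict:
        d = {"Sn": self.sn, "Sp": self.sp, "Acc": self.acc, "MCC": self.mcc}
        if self.auc is not None:
            d["AUC"] = self.auc
        return d


def _check_labels_scores(labels, scores):
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return labels, scores


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts with scores >= threshold predicted as class 1."""
    labels, scores = _check_labels_scores(labels, scores)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def metrics_from_counts(c: ConfusionCounts) -> MetricSet:
    """Sn, Sp, Acc and MCC from confusion counts.

    A zero MCC denominator (any margin empty) yields MCC = 0 with a warning;
    Sn/Sp are likewise 0 when their class is absent.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics over zero samples")
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    acc = (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fn) * (c.tn + c.fn) * (c.tp + c.fp) * (c.tn + c.fp)
    )
    if denom == 0:
        warnings.warn("MCC denominator is zero; reporting MCC = 0")
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return MetricSet(sn=sn, sp=sp, acc=acc, mcc=mcc)


def roc_auc(labels, scores) -> float:
    """Rank-based AUC (Mann–Whitney U / (n_pos · n_neg)), ties as 1/2."""
    labels, scores = _check_labels_scores(labels, scores)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate_scores(labels, scores, threshold: float = 0.5) -> MetricSet:
    """Full metric set (Sn, Sp, Acc, MCC, AUC) from labels and scores."""
    base = metrics_from_counts(confusion(labels, scores, threshold))
    return MetricSet(base.sn, base.sp, base.acc, base.mcc, roc_auc(labels, scores))


def _metric_fn(metric: str):
    if metric in ("accuracy", "acc"):
        return lambda y, s: metrics_from_counts(confusion(y, s)).acc
    if metric == "auc":
        return roc_auc
    raise ValueError(f"unknown importance metric {metric!r}")


def permutation_importance(
    model,
    X: pd.DataFrame,
    labels,
    metric: str = "accuracy",
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean ± SD drop in a metric when one column is shuffled.

    For each feature, its values are permuted ``n_repeats`` times (all other
    columns fixed) and the drop from the baseline metric recorded.  Positive
    importance means the model relies on the feature; negative values are
    possible (a shuffle can improve the metric by chance).

    Returns a DataFrame with columns ``feature``, ``mean``, ``sd``.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    labels = np.asarray(labels, dtype=int)
    fn = _metric_fn(metric)
    baseline = fn(labels, model.predict_score(X))
    rng = np.random.default_rng(seed)
    rows = []
    work = X.copy()
    for col in X.columns:
        original = work[col].to_numpy().copy()
        drops = np.empty(n_repeats)
        for r in range(n_repeats):
            work[col] = rng.permutation(original)
            drops[r] = baseline - fn(labels, model.predict_score(work))
        work[col] = original
        rows.append((col, float(drops.mean()), float(drops.std(ddof=0))))
    return pd.DataFrame(rows, columns=["feature", "mean", "sd"])
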