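"""The end-to-end fusion classifier: encode → rank → select → fuse → train.

:class:`FusionPipeline` is a scikit-learn style classifier over raw protein
sequences.  At fit time it encodes the training sequences with all seven
descriptors, ranks each descriptor's features by ANOVA F, runs sequential
backward selection per descriptor (CTD is kept whole by default), fuses the
chosen subsets in a fixed descriptor order, and trains the configured
classifier (MLP by default) on the fused matrix.  Prediction re-encodes new
sequences and applies the stored per-descriptor feature subsets, so the
fitted object is a complete sequence-in / score-out model.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .classify import ThermophilicityClassifier
from .descriptors import DESCRIPTOR_ORDER, build_encoders, encode_dataset
from .metrics import MetricSet, evaluate_scores
from .selection import SelectionResult, SequentialBackwardSelector, fuse
from .seqio import LabeledDataset


class FusionPipeline(ClassifierMixin, BaseEstimator):
    """Multi-descriptor fusion classifier over protein sequences.

    Parameters
    ----------
    lam, weight:
        λ and weight of both pseudo-amino-acid-composition descriptors.
    k_max:
        Largest gap of the k-spaced pair descriptor.
    ctd_grouping:
        Named or explicit 3-group residue partition for CTD.
    selection:
        If False, every descriptor contributes all its features.
    skip_selection:
        Descriptors fused whole even when selection is on (default CTD, whose
        performance degrades under selection).
    selection_step, selection_folds, selection_classifier, selection_epochs,
    selection_min_size:
        Backward-selection settings; the criterion is stratified
        ``selection_folds``-fold cross-validated AUC of the named inner
        classifier (``logreg`` default for speed, ``mlp`` available).
    classifier, epochs:
        Final classifier kind (mlp / svm / rf / knn) and MLP epochs.
    random_state:
        Single seed for selection folds and classifier initialisation.

    Attributes (after fit)
    ----------------------
    selections_ : dict of per-descriptor :class:`SelectionResult`.
    chosen_ : dict of per-descriptor chosen column names.
    feature_names_ : fused column names in fusion order.
    classifier_ : the fitted :class:`ThermophilicityClassifier`.
    """

    def __init__(
        self,
        lam: int = 4,
        weight: float = 0.05,
        k_max: int = 5,
        ctd_grouping="hydrophobicity",
        selection: bool = True,
        skip_selection: Sequence[str] = ("CTD",),
        selection_step: float = 0.05,
        selection_folds: int = 5,
        selection_classifier: str = "logreg",
        selection_epochs: int = 150,
        selection_min_size: int = 1,
        classifier: str = "mlp",
        epochs: int = 1200,
        random_state: int = 0,
    ):
        self.lam = lam
        self.weight = weight
        self.k_max = k_max
        self.ctd_grouping = ctd_grouping
        self.selection = selection
        self.skip_selection = skip_selection
        self.selection_step = selection_step
        self.selection_folds = selection_folds
        self.selection_classifier = selection_classifier
        self.selection_epochs = selection_epochs
        self.selection_min_size = selection_min_size
        self.classifier = classifier
        self.epochs = epochs
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _encoders(self):
        return build_encoders(
            lam=self.lam,
            weight=self.weight,
            k_max=self.k_max,
            ctd_grouping=self.ctd_grouping,
        )

    def _encode(self, sequences) -> dict[str, pd.DataFrame]:
        if isinstance(sequences, LabeledDataset):
            sequences = list(sequences)
        return encode_dataset(list(sequences), self._encoders())

    # -- estimator API -----------------------------------------------------

    def fit(self, sequences, y):
        """Fit on raw sequences (strings or records) and binary labels."""
        y = np.asarray(y, dtype=int)
        matrices = self._encode(sequences)
        skip = set(self.skip_selection)
        self.selections_ = {}
        self.chosen_ = {}
        restricted = {}
        for name in DESCRIPTOR_ORDER:
            X = matrices[name]
            if not self.selection or name in skip:
                self.chosen_[name] = list(X.columns)
                restricted[name] = X
                continue
            selector = SequentialBackwardSelector(
                step=self.selection_step,
                min_size=self.selection_min_size,
                classifier=self.selection_classifier,
                folds=self.selection_folds,
                epochs=self.selection_epochs,
                random_state=self.random_state,
            ).fit(X, y)
            self.selections_[name] = selector.result(name)
            self.chosen_[name] = list(selector.chosen_)
            restricted[name] = X[selector.chosen_]
        fused = fuse(restricted, order=DESCRIPTOR_ORDER)
        self.feature_names_ = list(fused.columns)
        self.classifier_ = ThermophilicityClassifier(
            kind=self.classifier, epochs=self.epochs, random_state=self.random_state
        ).fit(fused, y)
        self.classes_ = self.classifier_.classes_
        return self

    def transform(self, sequences) -> pd.DataFrame:
        """Fused feature matrix for new sequences under the fitted contract."""
        matrices = self._encode(sequences)
        restricted = {
            name: matrices[name][self.chosen_[name]] for name in DESCRIPTOR_ORDER
        }
        return fuse(restricted, order=DESCRIPTOR_ORDER)

    def predict_score(self, sequences) -> np.ndarray:
        """Thermophilic-class probability for each sequence."""
        return self.classifier_.predict_score(self.transform(sequences))

    def predict_proba(self, sequences) -> np.ndarray:
        return self.classifier_.predict_proba(self.transform(sequences))

    def predict(self, sequences) -> np.ndarray:
        return (self.predict_score(sequences) >= 0.5).astype(int)

    # -- reconstruction from artifacts -------------------------------------

    @classmethod
    def from_components(
        cls,
        params: Mapping,
        chosen: Mapping[str, Sequence[str]],
        classifier_: ThermophilicityClassifier,
        selections: Mapping[str, SelectionResult] | None = None,
    ) -> "FusionPipeline":
        """Rebuild a fitted pipeline from staged artifacts (selection JSONs +
        a classifier trained on the fused matrix)."""
        pipe = cls(**params)
        pipe.chosen_ = {k: list(v) for k, v in chosen.items()}
        pipe.selections_ = dict(selections or {})
        pipe.classifier_ = classifier_
        pipe.feature_names_ = list(classifier_.feature_names_ or [])
        pipe.classes_ = classifier_.classes_
        return pipe


def evaluate_pipeline(pipe: FusionPipeline, sequences, y, threshold: float = 0.5) -> MetricSet:
    """Held-out metric set (Sn, Sp, Acc, MCC, AUC) of a fitted pipeline."""
    return evaluate_scores(np.asarray(y, dtype=int), pipe.predict_score(sequences), threshold)
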