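"""Seven numeric sequence descriptors for protein classification.

Each encoder maps a residue string over the canonical alphabet to a fixed-
length, named feature vector:

========  ==============================================  ==============
name      descriptor                                      dimensionality
========  ==============================================  ==============
AAC       amino acid composition                          20
tPseAAC   traditional pseudo amino acid composition       20 + λ
aPseAAC   amphiphilic pseudo amino acid composition       20 + 2λ
CKSAAP    composition of k-spaced amino acid pairs        400·(k_max+1)
DC        dipeptide composition                           400
DDE       dipeptide deviation from expected mean          400
CTD       composition / transition / distribution         3 + 3 + 15
========  ==============================================  ==============

Feature order is fixed (alphabetical residues, lexicographic pairs, gap
blocks in ascending k) so that feature matrices are reproducible across runs.
Encoders are pure functions of the sequence: same input, bit-identical output.

Encoders are exposed both as scikit-learn transformers (``fit``/``transform``
over a list of sequences) and as per-sequence module functions; the functions
are thin wrappers over the transformer classes.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .properties import (
    ALPHABET,
    RESIDUE_INDEX,
    codon_fraction,
    ctd_grouping,
    normalized_properties,
)
from .seqio import LabeledDataset, ProteinRecord

#: Fixed descriptor order used for fusion and reporting.
DESCRIPTOR_ORDER = ("AAC", "tPseAAC", "aPseAAC", "CKSAAP", "DC", "DDE", "CTD")

_PAIR_NAMES = ["".join(p) for p in product(ALPHABET, repeat=2)]


def _indices(sequence: str) -> np.ndarray:
    try:
        return np.array([RESIDUE_INDEX[c] for c in sequence], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r} in sequence") from None


def _as_sequence(x) -> str:
    return x.sequence if isinstance(x, ProteinRecord) else str(x)


class BaseSequenceEncoder(TransformerMixin, BaseEstimator):
    """Common machinery: stateless fit, row-wise transform, named output."""

    name: str = ""

    def fit(self, X, y=None):  # noqa: D102 - stateless
        return self

    def feature_names(self) -> list[str]:
        raise NotImplementedError

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.feature_names(), dtype=object)

    def encode(self, sequence: str) -> np.ndarray:
        raise NotImplementedError

    def min_length(self) -> int:
        """Shortest sequence this encoder accepts."""
        return 1

    def transform(self, X: Iterable) -> np.ndarray:
        rows = [self.encode(_as_sequence(x)) for x in X]
        if not rows:
            raise ValueError("cannot encode an empty record collection")
        return np.vstack(rows)


class AACEncoder(BaseSequenceEncoder):
    """Amino acid composition: the 20 residue occurrence frequencies."""

    name = "AAC"

    def feature_names(self):
        return list(ALPHABET)

    def encode(self, sequence):
        idx = _indices(sequence)
        if idx.size == 0:
            raise ValueError("cannot encode an empty sequence")
        return np.bincount(idx, minlength=20) / idx.size


class DCEncoder(BaseSequenceEncoder):
    """Dipeptide composition: frequencies of the 400 ordered residue pairs
    among the N−1 overlapping adjacent pairs."""

    name = "DC"

    def feature_names(self):
        return list(_PAIR_NAMES)

    def min_length(self):
        return 2

    def encode(self, sequence):
        idx = _indices(sequence)
        if idx.size < 2:
            raise ValueError("dipeptide composition needs length >= 2")
        pairs = idx[:-1] * 20 + idx[1:]
        return np.bincount(pairs, minlength=400) / (idx.size - 1)


class CKSAAPEncoder(BaseSequenceEncoder):
    """Composition of k-spaced amino acid pairs, k = 0..k_max.

    For gap k the N−k−1 pairs (i, i+k+1) are counted and the 400-entry block
    is normalised by its own valid-pair count, so every block sums to 1.
    """

    def __init__(self, k_max: int = 5):
        self.k_max = k_max

    name = "CKSAAP"

    def feature_names(self):
        return [f"k{k}.{p}" for k in range(self.k_max + 1) for p in _PAIR_NAMES]

    def min_length(self):
        return self.k_max + 2

    def encode(self, sequence):
        idx = _indices(sequence)
        n = idx.size
        if n < self.k_max + 2:
            raise ValueError(
                f"CKSAAP with k_max={self.k_max} needs length >= {self.k_max + 2}, "
                f"got {n}"
            )
        blocks = []
        for k in range(self.k_max + 1):
            pairs = idx[: n - k - 1] * 20 + idx[k + 1 :]
            blocks.append(np.bincount(pairs, minlength=400) / (n - k - 1))
        return np.concatenate(blocks)


class DDEEncoder(BaseSequenceEncoder):
    """Dipeptide deviation from the expected mean.

    Each dipeptide frequency is centred on its codon-usage expectation
    Tm(g,h) = (Cg/CN)·(Ch/CN) and scaled by sqrt(Tv) with
    Tv = Tm·(1−Tm)/(N−1), where Cg counts the sense codons of residue g and
    CN = 61.  Values may be negative.
    """

    name = "DDE"

    def __init__(self):
        frac = codon_fraction()
        self._tm = np.outer(frac, frac).ravel()

    def feature_names(self):
        return list(_PAIR_NAMES)

    def min_length(self):
        return 2

    def encode(self, sequence):
        idx = _indices(sequence)
        n = idx.size
        if n < 2:
            raise ValueError("DDE needs length >= 2")
        dc = np.bincount(idx[:-1] * 20 + idx[1:], minlength=400) / (n - 1)
        tv = self._tm * (1.0 - self._tm) / (n - 1)
        return (dc - self._tm) / np.sqrt(tv)


class TPseAACEncoder(BaseSequenceEncoder):
    """Traditional pseudo amino acid composition (20 + λ dimensions).

    The first 20 entries are the weighted residue frequencies; the last λ are
    weighted tier-k sequence-correlation factors

        τ_k = mean_i J(R_i, R_{i+k}),   k = 1..λ,

    where J is the mean of squared differences of the standardised
    hydrophobicity, hydrophilicity and side-chain mass of the two residues.
    All 20+λ entries sum to 1; τ_k ≥ 0 by construction.
    """

    name = "tPseAAC"

    def __init__(self, lam: int = 4, weight: float = 0.05):
        self.lam = lam
        self.weight = weight

    def feature_names(self):
        return list(ALPHABET) + [f"tau{k}" for k in range(1, self.lam + 1)]

    def min_length(self):
        return self.lam + 1

    def encode(self, sequence):
        idx = _indices(sequence)
        n = idx.size
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if n <= self.lam:
            raise ValueError(
                f"lambda must be smaller than sequence length (lam={self.lam}, N={n})"
            )
        freqs = np.bincount(idx, minlength=20) / n
        props = normalized_properties()[:, idx]  # (3, N)
        taus = np.empty(self.lam)
        for k in range(1, self.lam + 1):
            diff = props[:, : n - k] - props[:, k:]
            taus[k - 1] = np.mean(diff**2, axis=0).mean()
        denom = 1.0 + self.weight * taus.sum()
        return np.concatenate([freqs, self.weight * taus]) / denom


class APseAACEncoder(BaseSequenceEncoder):
    """Amphiphilic pseudo amino acid composition (20 + 2λ dimensions).

    The 2λ sequence-order entries are the lagged correlation factors of the
    standardised hydrophobicity (H1) and hydrophilicity (H2), alternating
    H1/H2 per lag:

        τ_{2k−1} = mean_i H1(R_i)·H1(R_{i+k}),
        τ_{2k}   = mean_i H2(R_i)·H2(R_{i+k}).

    Correlation entries may be negative; all 20+2λ entries sum to 1.
    """

    name = "aPseAAC"

    def __init__(self, lam: int = 4, weight: float = 0.05):
        self.lam = lam
        self.weight = weight

    def feature_names(self):
        tail = []
        for k in range(1, self.lam + 1):
            tail += [f"tau{k}.H1", f"tau{k}.H2"]
        return list(ALPHABET) + tail

    def min_length(self):
        return self.lam + 1

    def encode(self, sequence):
        idx = _indices(sequence)
        n = idx.size
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if n <= self.lam:
            raise ValueError(
                f"lambda must be smaller than sequence length (lam={self.lam}, N={n})"
            )
        freqs = np.bincount(idx, minlength=20) / n
        h = normalized_properties()[:2, idx]  # H1, H2 rows
        taus = np.empty(2 * self.lam)
        for k in range(1, self.lam + 1):
            prod = h[:, : n - k] * h[:, k:]
            taus[2 * k - 2] = prod[0].mean()
            taus[2 * k - 1] = prod[1].mean()
        denom = 1.0 + self.weight * taus.sum()
        return np.concatenate([freqs, self.weight * taus]) / denom


class CTDEncoder(BaseSequenceEncoder):
    """Composition, transition and distribution over a 3-group partition.

    With the default hydrophobicity partition (polar / neutral / hydrophobic):

    * C (3): fraction of residues in each group;
    * T (3): frequency of adjacent-pair transitions between each unordered
      group pair, over the N−1 adjacent pairs;
    * D (15): for each group, the positions — 1-based, as a percentage of N —
      of its first residue and of its 25/50/75/100-percentile occurrences
      (percentile index ``ceil(p·count)``); all five are 0 for an absent
      group.
    """

    name = "CTD"

    def __init__(self, grouping="hydrophobicity"):
        self.grouping = grouping

    def _resolved(self) -> Mapping[str, str]:
        return ctd_grouping(self.grouping)

    def feature_names(self):
        groups = list(self._resolved())
        names = [f"C.{g}" for g in groups]
        names += [
            f"T.{a}-{b}" for i, a in enumerate(groups) for b in groups[i + 1 :]
        ]
        for g in groups:
            names += [f"D.{g}.{p}" for p in ("first", "25", "50", "75", "100")]
        return names

    def min_length(self):
        return 2

    def encode(self, sequence):
        mapping = self._resolved()
        n = len(sequence)
        if n < 2:
            raise ValueError("CTD needs length >= 2")
        group_of = np.empty(20, dtype=np.int64)
        for gi, residues in enumerate(mapping.values()):
            for aa in residues:
                group_of[RESIDUE_INDEX[aa]] = gi
        g = group_of[_indices(sequence)]

        comp = np.bincount(g, minlength=3) / n

        trans = np.zeros(3)
        a, b = g[:-1], g[1:]
        mask = a != b
        lo = np.minimum(a[mask], b[mask])
        hi = np.maximum(a[mask], b[mask])
        # unordered pair -> slot: (0,1)->0, (0,2)->1, (1,2)->2
        slot = np.where((lo == 0) & (hi == 1), 0, np.where((lo == 0) & (hi == 2), 1, 2))
        for s in range(3):
            trans[s] = np.sum(slot == s)
        trans /= n - 1

        dist = np.zeros((3, 5))
        for gi in range(3):
            pos = np.flatnonzero(g == gi) + 1  # 1-based positions
            cnt = pos.size
            if cnt == 0:
                continue
            picks = [1] + [int(np.ceil(p * cnt)) for p in (0.25, 0.5, 0.75, 1.0)]
            dist[gi] = [pos[p - 1] * 100.0 / n for p in picks]

        return np.concatenate([comp, trans, dist.ravel()])


def build_encoders(
    lam: int = 4,
    weight: float = 0.05,
    k_max: int = 5,
    ctd_grouping="hydrophobicity",
) -> dict[str, BaseSequenceEncoder]:
    """Instantiate all seven encoders, keyed by name in fusion order."""
    encoders = [
        AACEncoder(),
        TPseAACEncoder(lam=lam, weight=weight),
        APseAACEncoder(lam=lam, weight=weight),
        CKSAAPEncoder(k_max=k_max),
        DCEncoder(),
        DDEEncoder(),
        CTDEncoder(grouping=ctd_grouping),
    ]
    return {e.name: e for e in encoders}


def encode_dataset(
    records: Sequence, encoders: Mapping[str, BaseSequenceEncoder] | None = None, **kwargs
) -> dict[str, pd.DataFrame]:
    """Encode a record collection with every descriptor.

    Returns one DataFrame per descriptor (rows = records in input order,
    indexed by record id; columns carry a descriptor prefix, e.g. ``AAC.A``).
    A sequence violating a descriptor's minimum length raises a ValueError
    naming the record and descriptor.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot encode an empty record collection")
    if encoders is None:
        encoders = build_encoders(**kwargs)
    ids = [r.id if isinstance(r, ProteinRecord) else f"seq{i}" for i, r in enumerate(records)]
    out = {}
    for name, enc in encoders.items():
        min_len = enc.min_length()
        for rid, rec in zip(ids, records):
            if len(_as_sequence(rec)) < min_len:
                raise ValueError(
                    f"record {rid!r} is too short for descriptor {name} "
                    f"(needs length >= {min_len})"
                )
        mat = enc.transform(records)
        cols = [f"{name}.{f}" for f in enc.feature_names()]
        out[name] = pd.DataFrame(mat, index=pd.Index(ids, name="id"), columns=cols)
    return out


# ---------------------------------------------------------------------------
# Per-sequence convenience functions (thin wrappers over the transformers).

def encode_aac(sequence: str) -> np.ndarray:
    return AACEncoder().encode(sequence)


def encode_dc(sequence: str) -> np.ndarray:
    return DCEncoder().encode(sequence)


def encode_cksaap(sequence: str, k_max: int = 5) -> np.ndarray:
    return CKSAAPEncoder(k_max=k_max).encode(sequence)


def encode_dde(sequence: str) -> np.ndarray:
    return DDEEncoder().encode(sequence)


def encode_tpseaac(sequence: str, lam: int = 4, weight: float = 0.05) -> np.ndarray:
    return TPseAACEncoder(lam=lam, weight=weight).encode(sequence)


def encode_apseaac(sequence: str, lam: int = 4, weight: float = 0.05) -> np.ndarray:
    return APseAACEncoder(lam=lam, weight=weight).encode(sequence)


def encode_ctd(sequence: str, grouping="hydrophobicity") -> np.ndarray:
    return CTDEncoder(grouping=grouping).encode(sequence)
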