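"""Reading, validating, writing and splitting labelled protein sequence sets.

Sequences travel as :class:`ProteinRecord` objects: an identifier, a residue
string over the 20-letter canonical alphabet, and an optional binary label
(1 = thermophilic, 0 = non-thermophilic).  Labels are attached either from two
per-class FASTA files or from a two-column TSV (id<TAB>{0,1}).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .properties import ALPHABET, AMBIGUOUS_RESIDUES

_VALID = set(ALPHABET)


class FastaParseError(ValueError):
    """Structurally malformed FASTA input."""


class ValidationError(ValueError):
    """A sequence violates the canonical-alphabet contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with an optional binary class label."""

    id: str
    sequence: str
    label: int | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.label not in (None, 0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LabeledDataset:
    """An ordered collection of fully labelled records with unique ids."""

    records: tuple[ProteinRecord, ...]

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes[:5]}")
        if any(r.label is None for r in self.records):
            raise ValueError("all records in a LabeledDataset must be labelled")

    @property
    def n_pos(self) -> int:
        return sum(r.label == 1 for r in self.records)

    @property
    def n_neg(self) -> int:
        return sum(r.label == 0 for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def read_fasta(path) -> list[ProteinRecord]:
    """Read a (possibly line-wrapped) FASTA file into unlabelled records.

    Sequences are upper-cased; entry order is preserved.  Structural problems
    — an empty file, sequence data before the first header, or a header with
    no sequence — raise :class:`FastaParseError` naming the offending line.
    """
    path = Path(path)
    text = path.read_text()
    _check_fasta_structure(text, path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def _check_fasta_structure(text: str, path: Path) -> None:
    lines = text.splitlines()
    if not any(line.strip() for line in lines):
        raise FastaParseError(f"{path}: empty FASTA file")
    header_line = None
    seen_seq = False
    seen_header = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if header_line is not None and not seen_seq:
                raise FastaParseError(
                    f"{path}: header at line {header_line} has no sequence"
                )
            header_line, seen_seq, seen_header = lineno, False, True
        else:
            if not seen_header:
                raise FastaParseError(
                    f"{path}: sequence data before first header at line {lineno}"
                )
            seen_seq = True
    if header_line is not None and not seen_seq:
        raise FastaParseError(f"{path}: header at line {header_line} has no sequence")


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    """Write records to ``path`` in FASTA format (fixed line width)."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def validate_record(record: ProteinRecord, policy: str = "reject") -> ProteinRecord | None:
    """Enforce the canonical 20-residue alphabet on one record.

    ``reject``
        raise :class:`ValidationError` naming the first bad residue/position;
    ``drop``
        return ``None`` for any record with a non-canonical residue;
    ``strip-nonstandard``
        remove the ambiguity codes B/J/O/U/X/Z, then re-validate.
    """
    if policy not in ("reject", "drop", "strip-nonstandard"):
        raise ValueError(f"unknown policy {policy!r}")
    seq = record.sequence
    if policy == "strip-nonstandard":
        seq = "".join(c for c in seq if c not in AMBIGUOUS_RESIDUES)
        record = replace(record, sequence=seq)
    for pos, ch in enumerate(seq, start=1):
        if ch not in _VALID:
            if policy == "drop":
                return None
            raise ValidationError(
                f"record {record.id!r}: non-canonical residue {ch!r} at position {pos}"
            )
    return record


def validate_records(records, policy: str = "reject") -> list[ProteinRecord]:
    """Apply :func:`validate_record` to every record, filtering drops."""
    out = []
    for rec in records:
        v = validate_record(rec, policy=policy)
        if v is not None:
            out.append(v)
    return out


def read_label_tsv(path) -> dict[str, int]:
    """Read a two-column id<TAB>label file into a dict."""
    labels = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: line {lineno}: expected 'id<TAB>label'")
        ident, lab = parts[0].strip(), parts[1].strip()
        if lab not in ("0", "1"):
            raise ValueError(f"{path}: line {lineno}: label must be 0 or 1, got {lab!r}")
        labels[ident] = int(lab)
    return labels


def write_label_tsv(dataset: LabeledDataset, path) -> None:
    with open(path, "w") as fh:
        for rec in dataset:
            fh.write(f"{rec.id}\t{rec.label}\n")


def attach_labels(records: Sequence[ProteinRecord], labels: dict[str, int]) -> LabeledDataset:
    """Attach TSV labels to records; every record must be covered."""
    missing = [r.id for r in records if r.id not in labels]
    if missing:
        raise ValueError(f"no label for records: {missing[:5]}")
    return LabeledDataset(
        tuple(replace(r, label=labels[r.id]) for r in records)
    )


def load_two_class_fasta(pos_path, neg_path, policy: str = "reject") -> LabeledDataset:
    """Build a labelled dataset from one FASTA per class (1 = thermophilic)."""
    pos = validate_records(read_fasta(pos_path), policy)
    neg = validate_records(read_fasta(neg_path), policy)
    recs = [replace(r, label=1) for r in pos] + [replace(r, label=0) for r in neg]
    return LabeledDataset(tuple(recs))


def drop_duplicate_sequences(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Keep the first record of each exact duplicate sequence (optional step)."""
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.sequence not in seen:
            seen.add(rec.sequence)
            out.append(rec)
    return out


def stratified_split(
    dataset: LabeledDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Deterministic per-class split into train/test partitions.

    The per-class train size is ``floor(n_class * fraction + 0.5)`` (round half
    up), clamped so that neither side of either class is empty.  Membership is
    decided by a seeded shuffle; the same seed always yields the same split.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    by_class = {0: [], 1: []}
    for i, rec in enumerate(dataset):
        by_class[rec.label].append(i)
    for lab, idx in by_class.items():
        if len(idx) < 2:
            raise ValueError(f"class {lab} has fewer than 2 members; cannot stratify")
    rng = np.random.default_rng(seed)
    train_idx: set[int] = set()
    for lab in (0, 1):
        idx = np.array(by_class[lab])
        n = len(idx)
        n_train = int(math.floor(n * train_fraction + 0.5))
        n_train = min(max(n_train, 1), n - 1)
        perm = rng.permutation(n)
        train_idx.update(idx[perm[:n_train]].tolist())
    train = tuple(r for i, r in enumerate(dataset) if i in train_idx)
    test = tuple(r for i, r in enumerate(dataset) if i not in train_idx)
    return LabeledDataset(train), LabeledDataset(test)
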