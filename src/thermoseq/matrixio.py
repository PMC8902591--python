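"""Tab-separated serialisation of feature matrices.

Layout: header row; first column ``id``; one column per named feature; a
final ``label`` column when labels are present.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def write_feature_tsv(X: pd.DataFrame, path, y=None) -> None:
    """Write a samples × features matrix (optionally with labels) to TSV."""
    out = X.copy()
    out.index.name = "id"
    if y is not None:
        y = np.asarray(y, dtype=int)
        if len(y) != len(out):
            raise ValueError("labels and matrix row counts differ")
        out["label"] = y
    out.to_csv(path, sep="\t")


def read_feature_tsv(path) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Read a TSV written by :func:`write_feature_tsv`; returns (X, labels)."""
    df = pd.read_csv(path, sep="\t", index_col="id")
    y = None
    if "label" in df.columns:
        y = df.pop("label").to_numpy(dtype=int)
    if df.isna().any().any():
        raise ValueError(f"{path}: feature matrix contains missing values")
    return df, y
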