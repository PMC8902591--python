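"""Physicochemical and genetic-code constants used by the sequence descriptors.

The pseudo-amino-acid-composition descriptors correlate residues through three
physicochemical indices — hydrophobicity (H1), hydrophilicity (H2) and
side-chain mass (M) — taken from the classic pseudo amino acid composition
formulation.  Each index is standardised to zero mean and unit population
standard deviation across the 20 canonical residues before use, so the three
properties contribute on a common scale.

The dipeptide-deviation descriptor needs the number of sense codons encoding
each residue under the standard genetic code (61 sense codons in total).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

#: Canonical residue alphabet, alphabetical; fixes feature order everywhere.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Index of each residue in :data:`ALPHABET`.
RESIDUE_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Non-canonical one-letter codes that may appear in real FASTA files.
AMBIGUOUS_RESIDUES = frozenset("BJOUXZ")

#: Sense codons per residue under the standard genetic code (sums to 61).
CODON_COUNTS = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2,
    "G": 4, "H": 2, "I": 3, "K": 2, "L": 6,
    "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6,
    "S": 6, "T": 4, "V": 4, "W": 1, "Y": 2,
}

#: Total number of sense codons.
CODON_TOTAL = 61

#: Named three-group residue partitions for the composition/transition/
#: distribution descriptor.  The default "hydrophobicity" grouping splits the
#: alphabet into polar, neutral and hydrophobic residues.
CTD_GROUPINGS: dict[str, dict[str, str]] = {
    "hydrophobicity": {
        "polar": "RKEDQN",
        "neutral": "GASTPHY",
        "hydrophobic": "CLVIMFW",
    },
}


@lru_cache(maxsize=None)
def load_property_table() -> pd.DataFrame:
    """Return the raw H1/H2/M table indexed by residue (alphabet order)."""
    ref = resources.files("thermoseq.data").joinpath("pseaac_properties.tsv")
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t", index_col="residue")
    table = table.loc[list(ALPHABET)]
    if len(table) != 20:
        raise ValueError("property table must cover exactly the 20 residues")
    return table


@lru_cache(maxsize=None)
def normalized_properties() -> np.ndarray:
    """H1/H2/M standardised over the 20 residues; shape (3, 20).

    Standardisation uses the population standard deviation (ddof=0), so each
    row has mean 0 and SD 1 exactly.
    """
    raw = load_property_table().to_numpy().T.astype(float)
    mean = raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, ddof=0, keepdims=True)
    return (raw - mean) / sd


def codon_fraction() -> np.ndarray:
    """Per-residue codon usage fraction Cg/CN in alphabet order."""
    return np.array([CODON_COUNTS[aa] for aa in ALPHABET], float) / CODON_TOTAL


def ctd_grouping(name_or_mapping) -> dict[str, str]:
    """Resolve a named or explicit 3-group partition and validate it.

    Parameters
    ----------
    name_or_mapping:
        Either a key of :data:`CTD_GROUPINGS` or a mapping of exactly three
        group names to residue strings that together partition the alphabet.
    """
    if isinstance(name_or_mapping, str):
        try:
            mapping = CTD_GROUPINGS[name_or_mapping]
        except KeyError:
            raise KeyError(
                f"unknown CTD grouping {name_or_mapping!r}; "
                f"known: {sorted(CTD_GROUPINGS)}"
            ) from None
    else:
        mapping = dict(name_or_mapping)
    if len(mapping) != 3:
        raise ValueError("CTD grouping must have exactly 3 groups")
    pooled = "".join(mapping.values())
    if sorted(pooled) != sorted(ALPHABET):
        raise ValueError("CTD grouping must partition the 20-residue alphabet")
    return mapping
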