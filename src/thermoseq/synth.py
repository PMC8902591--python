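"""Synthetic labelled protein datasets with controllable class structure.

The generator emulates the compositional signal that separates thermophilic
from mesophilic proteins: thermophile-like sequences are enriched in charged
and hydrophobic residues (K, E, D, Q, Y, I, V — salt-bridge formers and
core packers), mesophile-like sequences in small neutral residues
(A, T, S, G).  Starting from a uniform residue background, the effect size
``delta`` in [0, 1] tilts each class profile toward its enriched set; at
``delta = 0`` the two classes are statistically identical.

An optional first-order dipeptide coupling blends i.i.d. draws with
class-preferred dipeptides (KE, LK, EE, EK, KI, IK for positives; AA, LA for
negatives), adding pairwise structure that only the dipeptide-aware
descriptors can see.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .properties import ALPHABET, RESIDUE_INDEX
from .seqio import LabeledDataset, ProteinRecord

#: Residues enriched in the thermophile-like class (charged + hydrophobic).
THERMO_ENRICHED = "KEDQYIV"

#: Residues enriched in the mesophile-like class (small/neutral).
MESO_ENRICHED = "ATSG"

#: Class-preferred dipeptides used by the first-order coupling.
THERMO_PAIRS = ("KE", "LK", "EE", "EK", "KI", "IK")
MESO_PAIRS = ("AA", "LA")


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults define the package's study conditions."""

    n_pos: int = 200
    n_neg: int = 200
    length_range: tuple[int, int] = (50, 400)
    effect_size: float = 0.8
    dipeptide_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("class sizes must be non-negative")
        lo, hi = self.length_range
        if lo < 10 or hi < lo:
            raise ValueError("length range must satisfy 10 <= L_min <= L_max")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [0, 1]")
        if not 0.0 <= self.dipeptide_coupling <= 1.0:
            raise ValueError("dipeptide_coupling must lie in [0, 1]")


def make_profiles(delta: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue probability profiles for the two classes.

    Each enriched residue's weight grows from 1 to 1 + ``delta`` relative to
    the rest, then the profile is renormalised; ``delta = 0`` gives the
    uniform profile for both classes.

    Returns (thermophile-like profile, mesophile-like profile) in alphabet
    order, each summing to 1.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    profiles = []
    for enriched in (THERMO_ENRICHED, MESO_ENRICHED):
        w = np.ones(20)
        for aa in enriched:
            w[RESIDUE_INDEX[aa]] += delta
        profiles.append(w / w.sum())
    return profiles[0], profiles[1]


_LETTERS = np.array(list(ALPHABET))


def _draw_sequence(rng, length, profile, pairs, coupling) -> str:
    if coupling == 0.0:
        return "".join(_LETTERS[rng.choice(20, size=length, p=profile)])
    starters: dict[str, list[str]] = {}
    for a, b in pairs:
        starters.setdefault(a, []).append(b)
    out = [_LETTERS[rng.choice(20, p=profile)]]
    while len(out) < length:
        prev = out[-1]
        if prev in starters and rng.random() < coupling:
            succ = starters[prev]
            out.append(succ[rng.integers(len(succ))])
        else:
            out.append(_LETTERS[rng.choice(20, p=profile)])
    return "".join(out)


def generate(config: SynthConfig) -> LabeledDataset:
    """Generate a labelled dataset under ``config``; fixed seed, fixed output.

    Positives come first (ids ``POS_0001`` …), then negatives (``NEG_0001``
    …); lengths are uniform over the configured range.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    pos_profile, neg_profile = make_profiles(config.effect_size)
    records = []
    for prefix, n, profile, pairs, label in (
        ("POS", config.n_pos, pos_profile, THERMO_PAIRS, 1),
        ("NEG", config.n_neg, neg_profile, MESO_PAIRS, 0),
    ):
        lengths = rng.integers(lo, hi + 1, size=n)
        for i in range(n):
            seq = _draw_sequence(
                rng, int(lengths[i]), profile, pairs, config.dipeptide_coupling
            )
            records.append(ProteinRecord(f"{prefix}_{i + 1:04d}", seq, label))
    return LabeledDataset(tuple(records))
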