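"""Independent brute-force reference implementations used as test oracles.

Everything here is written naively — dict counters, explicit Python loops,
literal formulas — and deliberately shares no code path with the package
(only the raw physicochemical table and codon counts, which are data, are
reused).  The oracles exist to cross-check the vectorised encoders, the
ANOVA decomposition and the metric formulas.
"""

from __future__ import annotations

import math
from itertools import product

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
PAIRS = ["".join(p) for p in product(ALPHABET, repeat=2)]

CODONS = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3, "K": 2,
    "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6, "T": 4, "V": 4,
    "W": 1, "Y": 2,
}

RAW_PROPS = {  # residue -> (hydrophobicity, hydrophilicity, side-chain mass)
    "A": (0.62, -0.5, 15.0), "C": (0.29, -1.0, 47.0), "D": (-0.90, 3.0, 59.0),
    "E": (-0.74, 3.0, 73.0), "F": (1.19, -2.5, 91.0), "G": (0.48, 0.0, 1.0),
    "H": (-0.40, -0.5, 82.0), "I": (1.38, -1.8, 57.0), "K": (-1.50, 3.0, 73.0),
    "L": (1.06, -1.8, 57.0), "M": (0.64, -1.3, 75.0), "N": (-0.78, 0.2, 58.0),
    "P": (0.12, 0.0, 42.0), "Q": (-0.85, 0.2, 72.0), "R": (-2.53, 3.0, 101.0),
    "S": (-0.18, 0.3, 31.0), "T": (-0.05, -0.4, 45.0), "V": (1.08, -1.5, 43.0),
    "W": (0.81, -3.4, 130.0), "Y": (0.26, -2.3, 107.0),
}


def _norm_props():
    """Standardise the three property columns over the 20 residues."""
    out = {}
    for j in range(3):
        vals = [RAW_PROPS[aa][j] for aa in ALPHABET]
        mean = sum(vals) / 20.0
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 20.0)
        for aa in ALPHABET:
            out.setdefault(aa, []).append((RAW_PROPS[aa][j] - mean) / sd)
    return out


NORM_PROPS = _norm_props()


def oracle_aac(seq):
    return [seq.count(aa) / len(seq) for aa in ALPHABET]


def oracle_dc(seq):
    counts = {p: 0 for p in PAIRS}
    for i in range(len(seq) - 1):
        counts[seq[i : i + 2]] += 1
    return [counts[p] / (len(seq) - 1) for p in PAIRS]


def oracle_cksaap(seq, k_max=5):
    out = []
    for k in range(k_max + 1):
        counts = {p: 0 for p in PAIRS}
        n_k = len(seq) - k - 1
        for i in range(n_k):
            counts[seq[i] + seq[i + k + 1]] += 1
        out.extend(counts[p] / n_k for p in PAIRS)
    return out


def oracle_dde(seq):
    n = len(seq)
    dc = oracle_dc(seq)
    out = []
    for pair, d in zip(PAIRS, dc):
        tm = (CODONS[pair[0]] / 61.0) * (CODONS[pair[1]] / 61.0)
        tv = tm * (1.0 - tm) / (n - 1)
        out.append((d - tm) / math.sqrt(tv))
    return out


def _oracle_j(a, b):
    pa, pb = NORM_PROPS[a], NORM_PROPS[b]
    return sum((pa[j] - pb[j]) ** 2 for j in range(3)) / 3.0


def oracle_tpseaac(seq, lam=4, w=0.05):
    n = len(seq)
    freqs = oracle_aac(seq)
    taus = []
    for k in range(1, lam + 1):
        taus.append(sum(_oracle_j(seq[i], seq[i + k]) for i in range(n - k)) / (n - k))
    denom = sum(freqs) + w * sum(taus)
    return [f / denom for f in freqs] + [w * t / denom for t in taus]


def oracle_apseaac(seq, lam=4, w=0.05):
    n = len(seq)
    freqs = oracle_aac(seq)
    taus = []
    for k in range(1, lam + 1):
        h1 = sum(NORM_PROPS[seq[i]][0] * NORM_PROPS[seq[i + k]][0] for i in range(n - k))
        h2 = sum(NORM_PROPS[seq[i]][1] * NORM_PROPS[seq[i + k]][1] for i in range(n - k))
        taus.extend([h1 / (n - k), h2 / (n - k)])
    denom = sum(freqs) + w * sum(taus)
    return [f / denom for f in freqs] + [w * t / denom for t in taus]


CTD_GROUPS = {"polar": "RKEDQN", "neutral": "GASTPHY", "hydrophobic": "CLVIMFW"}


def oracle_ctd(seq):
    n = len(seq)
    names = list(CTD_GROUPS)
    of = {aa: g for g, aas in CTD_GROUPS.items() for aa in aas}
    comp = [sum(of[c] == g for c in seq) / n for g in names]
    trans = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            t = sum(
                {of[seq[j]], of[seq[j + 1]]} == {a, b} for j in range(n - 1)
            )
            trans.append(t / (n - 1))
    dist = []
    for g in names:
        pos = [i + 1 for i, c in enumerate(seq) if of[c] == g]
        if not pos:
            dist.extend([0.0] * 5)
            continue
        cnt = len(pos)
        picks = [1] + [math.ceil(p * cnt) for p in (0.25, 0.5, 0.75, 1.0)]
        dist.extend(pos[p - 1] * 100.0 / n for p in picks)
    return comp + trans + dist


def oracle_anova_f(values_by_group):
    """Literal two-group one-way ANOVA for one feature (lists of floats)."""
    k = len(values_by_group)
    all_vals = [v for g in values_by_group for v in g]
    n = len(all_vals)
    grand = sum(all_vals) / n
    ss_b = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in values_by_group)
    ss_w = sum(
        sum((v - sum(g) / len(g)) ** 2 for v in g) for g in values_by_group
    )
    s2b = ss_b / (k - 1)
    s2w = ss_w / (n - k)
    if s2w == 0:
        return math.inf if s2b > 0 else 0.0
    return s2b / s2w


def oracle_auc(labels, scores):
    """All-pairs AUC: P(score_pos > score_neg) with ties counted 1/2."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def oracle_metrics(tp, tn, fp, fn):
    """Literal Sn/Sp/Acc/MCC formulas."""
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / (tp + tn + fp + fn)
    denom = (tp + fn) * (tn + fn) * (tp + fp) * (tn + fp)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return sn, sp, acc, mcc


def random_peptide(rng, min_len=10, max_len=60):
    length = int(rng.integers(min_len, max_len + 1))
    return "".join(ALPHABET[i] for i in rng.integers(0, 20, size=length))
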