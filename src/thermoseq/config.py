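"""Pipeline configuration: defaults, YAML round-trip, canonical hashing.

A single YAML file drives every CLI stage.  All randomness is seeded
explicitly from the config (no wall-clock seeding), and the canonical SHA-256
hash of the merged config is stamped into every stage manifest so runs are
auditable and reproducible.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "data": {
        # either a synth block, or pos_fasta/neg_fasta (+ optional labels TSV)
        "synth": {
            "n_pos": 200,
            "n_neg": 200,
            "length_range": [50, 400],
            "effect_size": 0.8,
            "dipeptide_coupling": 0.0,
        },
        "pos_fasta": None,
        "neg_fasta": None,
        "labels": None,
        "ambiguity_policy": "reject",
        "drop_duplicates": False,
    },
    "split": {"train_fraction": 0.8},
    "descriptors": {
        "lam": 4,
        "weight": 0.05,
        "k_max": 5,
        "ctd_grouping": "hydrophobicity",
    },
    "selection": {
        "enabled": True,
        "skip": ["CTD"],
        "step": 0.05,
        "folds": 5,
        "classifier": "logreg",
        "epochs": 150,
        "min_size": 1,
    },
    "classifier": {"kind": "mlp", "epochs": 1200},
    "evaluation": {
        "importance_repeats": 10,
        "importance_metric": "accuracy",
        "threshold": 0.5,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file (and explicit overrides) onto the defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """SHA-256 of the canonical JSON form of the config."""
    canon = json.dumps(cfg, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def write_manifest(directory, stage: str, cfg: dict, extra: dict | None = None) -> Path:
    """Write a stage manifest (config hash + stage outputs); returns its path.

    Manifests are deliberately free of timestamps so identical runs produce
    byte-identical manifests.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "config_hash": config_hash(cfg),
        "seed": cfg.get("seed"),
    }
    if extra:
        manifest.update(extra)
    path = directory / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path
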