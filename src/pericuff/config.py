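"""Run configuration and provenance logging.

A run is a pure function of (config, seed).  Every run writes a JSON
metadata record holding the master seed, a hash of the resolved config and
checksums of all file inputs, so that outputs can be traced back exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__


def load_config(path) -> dict:
    """Load a YAML config file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def _canonical(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _canonical(asdict(obj))
    if isinstance(obj, dict):
        return {k: _canonical(obj[k]) for k in sorted(obj)}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_hash(cfg) -> str:
    """Stable sha256 over a config mapping/dataclass (order-insensitive)."""
    blob = json.dumps(_canonical(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_run_metadata(out_dir, seed: int, cfg, inputs=()) -> Path:
    """Write the run-metadata JSON record and return its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "software": "pericuff",
        "version": __version__,
        "seed": int(seed),
        "config_hash": config_hash(cfg),
        "config": _canonical(cfg),
        "input_checksums": {str(p): file_checksum(p) for p in inputs},
    }
    path = out_dir / "run_metadata.json"
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)
    return path


def substream(seed: int, stage: str) -> np.random.Generator:
    """Named pseudorandom substream derived from the master seed.

    Each pipeline stage draws from its own stream so results for one stage
    are reproducible even when unrelated config changes alter the draw
    counts of other stages.
    """
    tag = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
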