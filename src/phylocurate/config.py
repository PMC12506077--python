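"""Layered configuration and run manifests.

Configuration resolves as built-in defaults < YAML config file < command
line flags; the resolved snapshot is frozen into a per-run manifest JSON
together with input-file digests, the seed, and the output inventory, so
any run can be audited and re-executed.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

#: Shipped defaults. The homology-score cutoff parameterises the hook for
#: an external per-sequence alignment-confidence filter; nothing in this
#: package computes that score.
DEFAULTS: dict[str, Any] = {
    "sister_multiplier": 0.5,
    "gap_mask_strict": 0.95,
    "gap_mask_lenient": 0.50,
    "similarity_cutoff": 0.99,
    "relative_length_lower": 1.0 / 3.0,
    "relative_length_upper": 1.5,
    "homology_score_cutoff": 0.3,
    "outgroup_prefixes": ["Ba", "Za"],
    "branch_stat": "terminal",
    "egt_min_clade_leaves": 4,
    "egt_min_photo_minors": 3,
    "max_iterations": 10,
}


def load_config(path: str | Path | None = None, overrides: Mapping[str, Any] | None = None) -> dict:
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        cfg.update(user)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Accumulates one run's provenance and writes it as JSON."""

    def __init__(self, command: str, config: Mapping[str, Any], seed: int | None = None):
        from phylocurate import __version__

        self.data: dict[str, Any] = {
            "command": command,
            "config": dict(config),
            "seed": seed,
            "tool_version": __version__,
            "started": datetime.datetime.now().isoformat(timespec="seconds"),
            "inputs": {},
            "outputs": [],
        }

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.data["inputs"][str(p)] = file_digest(p)

    def add_output(self, path: str | Path) -> None:
        self.data["outputs"].append(str(path))

    def write(self, path: str | Path) -> None:
        self.data["finished"] = datetime.datetime.now().isoformat(timespec="seconds")
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")
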