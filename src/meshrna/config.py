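"""Flat key=value run configuration.

Precedence: CLI overrides > config file > defaults.  Unknown keys are
rejected; the effective configuration (and its short hash) is echoed into
every output header so runs are reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Dict, Optional, Union

DEFAULTS: Dict[str, str] = {
    "energy.kind": "stacking",
    "energy.temperature_K": "310.15",
    "fold.min_hairpin": "3",
    "fold.max_length": "7500",
    "ldr.tau": "0.5",
    "ldr.min_length": "30",
    "classifier.hi": "0.280",
    "classifier.lo": "0.265",
    "classifier.gap_rule": "nearest",
    "stats.continuity": "false",
    "are.overlapping": "true",
    "clip.strand_mode": "aware",
    "clip.min_overlap": "1",
    "clip.union_rule": "max",
    "seed": "0",
}


class ConfigError(ValueError):
    pass


def load_config(
    path: Optional[Union[str, Path]] = None,
    overrides: Optional[Dict[str, str]] = None,
) -> Dict[str, str]:
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            for ln, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{ln}: expected key=value")
                key, value = (s.strip() for s in line.split("=", 1))
                if key not in DEFAULTS:
                    raise ConfigError(f"{path}:{ln}: unknown config key {key!r}")
                cfg[key] = value
    for key, value in (overrides or {}).items():
        if key not in DEFAULTS:
            raise ConfigError(f"unknown config key {key!r}")
        cfg[key] = str(value)
    return cfg


def config_hash(cfg: Dict[str, str]) -> str:
    blob = "\n".join(f"{k}={cfg[k]}" for k in sorted(cfg))
    return hashlib.sha256(blob.encode()).hexdigest()[:10]


def as_bool(value: str) -> bool:
    if value.lower() in ("true", "1", "yes"):
        return True
    if value.lower() in ("false", "0", "no"):
        return False
    raise ConfigError(f"expected a boolean, got {value!r}")
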