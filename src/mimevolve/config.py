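"""Pipeline configuration: one flat YAML file, explicit seeds, no hidden state.

Unknown keys are rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Seeds, colour cuts, bootstrap size, era windows and paths for a run."""

    output_dir: str = "results"
    seed_render: int = 11
    seed_pedigree: int = 12
    seed_series: int = 13
    seed_bootstrap: int = 14
    seed_fused_sampling: int = 15
    white_cut: float = 128.0
    achromatic_cut: float = 40.0
    red_margin: float = 50.0
    n_boot: int = 10000
    pre_end: int = 1991
    post_start: int = 1994
    n_wings: int = 6
    inheritance_mode: str = "w_linked"
    offspring_per_pair: int = 6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
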