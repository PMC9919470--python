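"""Run configuration shared by the CLI subcommands."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .architecture import COMPACT_THRESHOLD, LOOSE_THRESHOLD, AGGREGATION_MODES

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    units: str = "cm"
    loose_threshold: float = LOOSE_THRESHOLD
    compact_threshold: float = COMPACT_THRESHOLD
    aggregation: str = "mean"
    spike_fallback_fraction: float = 0.2
    tip_tolerance: float = 0.2
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.loose_threshold >= self.compact_threshold:
            raise ValueError("class thresholds must be ordered")
        if not 0.0 < self.spike_fallback_fraction < 1.0:
            raise ValueError("spike_fallback_fraction must lie in (0, 1)")
        if self.aggregation not in AGGREGATION_MODES:
            raise ValueError(f"aggregation must be one of {AGGREGATION_MODES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}; valid: {sorted(known)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Short stable hash of the configuration, for run logging."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
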