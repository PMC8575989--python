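"""Pipeline configuration: one YAML/JSON document driving every stage.

Every stochastic stage derives its seed deterministically from the master
seed and the stage name, so a config + seed pair reproduces the whole
pipeline byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .grid import ProbeGrid
from .synth import GroundTruthConfig

__all__ = ["PipelineConfig", "stage_seed", "load_config"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    grid: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)
    n_trials: int = 200
    pruning: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    decoding: dict = field(default_factory=dict)
    modulation_threshold: float = 0.3
    seed: int = 0

    def probe_grid(self) -> ProbeGrid:
        return ProbeGrid(**self.grid)

    def ground_truth_config(self) -> GroundTruthConfig:
        gt = dict(self.ground_truth)
        for key in ("rf1_time_range", "late_delay_range", "late_time_range",
                    "suppression_time_range", "history_weights"):
            if key in gt:
                gt[key] = tuple(gt[key])
        return GroundTruthConfig(**gt)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
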