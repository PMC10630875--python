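"""Pipeline configuration and run manifest.

Every tunable threshold lives here with its default; a run writes the
resolved configuration next to its outputs so results are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._align import Scoring
from .errors import ConfigError
from .lariat_detect import STAGE_ORDER, DetectParams


@dataclass
class PipelineConfig:
    min_intron_len: int = 300
    five_len: int = 20
    three_len: int = 250
    umi_len: int = 12
    min_segment: int = 20
    max_mismatches: int = 5
    max_mismatch_rate: float = 0.10
    max_indel: int = 3
    max_gap_runs: int = 4
    max_n_frac: float = 0.05
    subtract_strand: str = "same"
    umi_dedup: bool = False
    match_score: int = 0
    mismatch_cost: int = 1
    gap_open: int = 3
    gap_extend: int = 1
    seed: int = 1

    def __post_init__(self) -> None:
        if self.subtract_strand not in ("same", "both"):
            raise ConfigError("subtract_strand must be 'same' or 'both'")
        if not 0.0 <= self.max_n_frac <= 1.0:
            raise ConfigError("max_n_frac must lie in [0, 1]")

    def detect_params(self) -> DetectParams:
        return DetectParams(
            umi_len=self.umi_len,
            min_segment=self.min_segment,
            max_mismatches=self.max_mismatches,
            max_mismatch_rate=self.max_mismatch_rate,
            max_indel=self.max_indel,
            max_gap_runs=self.max_gap_runs,
            umi_dedup=self.umi_dedup,
            scoring=Scoring(
                match=self.match_score,
                mismatch=self.mismatch_cost,
                gap_open=self.gap_open,
                gap_extend=self.gap_extend,
            ),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def override(self, **kwargs) -> "PipelineConfig":
        """New config with non-None keyword overrides applied."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **updates)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def sha256_file(path: str | Path, chunk: int = 1 << 20) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        while True:
            block = fh.read(chunk)
            if not block:
                break
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    tool_version: str = ""
    input_checksums: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)  # sample_id -> {stage: n}

    def validate(self) -> None:
        order = ("input", "post_qc") + STAGE_ORDER[1:]
        for sample, counts in self.stage_counts.items():
            present = [counts[s] for s in order if s in counts]
            if any(a < b for a, b in zip(present, present[1:])):
                raise ConfigError(f"sample {sample}: stage counts increase")

    def write(self, path: str | Path) -> None:
        self.validate()
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)
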