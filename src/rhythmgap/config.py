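"""Experiment configuration: validated constants and YAML round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .warp import PHASE_SET

__all__ = ["ExperimentConfig"]


@dataclass(frozen=True)
class ExperimentConfig:
    """All constants of the stimulus and procedure, at their defaults.

    Every field is validated against its admissible range on
    construction, so a config loaded from file fails fast with the
    offending field named.
    """

    frame_ms: float = 50.0
    depth: float = 0.75
    cycles_low: int = 1
    cycles_high: int = 3
    phases: tuple[float, ...] = PHASE_SET
    isi_ms: tuple[float, float] = (400.0, 800.0)
    gap_ms_male: float = 1661.0
    gap_ms_female: float = 1603.0
    early_ms_male: float = 1200.0
    early_ms_female: float = 1150.0
    final_ms_male: float = 350.0
    final_ms_female: float = 330.0
    n_blocks: int = 3
    trials_per_block: int = 40
    start_early: float = 1.0
    start_late: float = 1.5
    bounds_early: tuple[float, float] = (0.0, 1.0)
    bounds_late: tuple[float, float] = (0.0, 2.0)
    n_reversals_for_threshold: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        checks = {
            "frame_ms": self.frame_ms > 0,
            "depth": 0.0 <= self.depth <= 1.0,
            "cycles_low": self.cycles_low >= 1,
            "cycles_high": self.cycles_high >= 1,
            "phases": all(0 <= p < 2 * math.pi for p in self.phases),
            "isi_ms": 0 < self.isi_ms[0] <= self.isi_ms[1],
            "gap_ms_male": self.gap_ms_male > 0,
            "gap_ms_female": self.gap_ms_female > 0,
            "early_ms_male": self.early_ms_male >= self.frame_ms,
            "early_ms_female": self.early_ms_female >= self.frame_ms,
            "final_ms_male": self.final_ms_male > 0,
            "final_ms_female": self.final_ms_female > 0,
            "n_blocks": self.n_blocks >= 1,
            "trials_per_block": self.trials_per_block >= 2
            and self.trials_per_block % 2 == 0,
            "start_early": self.bounds_early[0] <= self.start_early <= self.bounds_early[1],
            "start_late": self.bounds_late[0] <= self.start_late <= self.bounds_late[1],
            "bounds_early": self.bounds_early[0] < self.bounds_early[1],
            "bounds_late": self.bounds_late[0] < self.bounds_late[1],
            "n_reversals_for_threshold": self.n_reversals_for_threshold >= 1,
            "seed": 0 <= int(self.seed) < 2**31,
        }
        bad = [name for name, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid configuration field(s): {', '.join(bad)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phases"] = list(self.phases)
        d["isi_ms"] = list(self.isi_ms)
        d["bounds_early"] = list(self.bounds_early)
        d["bounds_late"] = list(self.bounds_late)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kwargs = dict(d)
        for name in ("phases", "isi_ms", "bounds_early", "bounds_late"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown configuration field(s): {', '.join(sorted(unknown))}")
        return cls(**kwargs)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """Stable hash of the configuration for run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
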