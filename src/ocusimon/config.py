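"""Run configuration: one YAML file drives the whole pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .design_sim import SimParams
from .saccade_detection import DetectorParams

__all__ = ["ExclusionParams", "RunConfig"]


@dataclass
class ExclusionParams:
    lo_ms: float = 100.0
    hi_ms: float = 1000.0
    sd_mult: float = 3.0

    def __post_init__(self) -> None:
        if self.lo_ms >= self.hi_ms:
            raise ValueError("lo_ms must be < hi_ms")
        if self.sd_mult <= 0:
            raise ValueError("sd_mult must be > 0")


@dataclass
class RunConfig:
    """Validated parameters for a full simulate→detect→analyze run."""

    seed: int
    n_participants: int = 43
    n_blocks: int = 5
    trials_per_block: int = 60
    sim: SimParams = field(default_factory=SimParams)
    detector: DetectorParams = field(default_factory=DetectorParams)
    exclusions: ExclusionParams = field(default_factory=ExclusionParams)
    n_bins: int = 7
    posthoc_method: str = "max-z"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must provide a seed")
        self.seed = int(self.seed)
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.trials_per_block % 4 != 0:
            raise ValueError("trials_per_block must be divisible by 4")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.posthoc_method not in ("max-z", "holm"):
            raise ValueError("posthoc_method must be 'max-z' or 'holm'")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {"seed", "n_participants", "n_blocks", "trials_per_block",
                 "sim", "detector", "exclusions", "n_bins", "posthoc_method"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in d:
            raise ValueError("config must provide a seed")
        if "sim" in d:
            d["sim"] = SimParams(**d["sim"])
        if "detector" in d:
            d["detector"] = DetectorParams(**d["detector"])
        if "exclusions" in d:
            d["exclusions"] = ExclusionParams(**d["exclusions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
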