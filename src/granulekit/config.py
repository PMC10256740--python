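"""Pipeline configuration: documented defaults, strict key checking,
YAML round-trip, and serialization alongside outputs."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class TrackingConfig:
    diameter_um: float = 0.5          # granule diameter for LoG scale
    quality_threshold: float | None = None  # None -> per-movie Otsu
    max_displacement_um: float = 0.5  # linking radius per frame
    min_frames: int = 21              # keep tracks > 20 frames
    rolling_ball_radius: int = 3


@dataclass
class DynamicsConfig:
    max_lag: int = 7
    convention: str = "slope/4"       # or "slope"


@dataclass
class CotransportConfig:
    min_run_um: float = 2.0
    max_gap_um: float = 0.5
    min_overlap_fraction: float = 0.5


@dataclass
class LocalizationConfig:
    expression_threshold: float = 1.0
    delta_threshold: float = 0.25
    min_spots: int = 150
    loess_span: float = 0.7
    loess_cycles: int = 3


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "granulekit_out"
    verbosity: int = 1
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    cotransport: CotransportConfig = field(default_factory=CotransportConfig)
    localization: LocalizationConfig = field(default_factory=LocalizationConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        for key, val in d.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key {key!r}")
            cur = getattr(cfg, key)
            if dataclasses.is_dataclass(cur):
                names = {f.name for f in dataclasses.fields(cur)}
                unknown = set(val) - names
                if unknown:
                    raise KeyError(f"unknown keys in {key!r}: {sorted(unknown)}")
                setattr(cfg, key, type(cur)(**val))
            else:
                setattr(cfg, key, val)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path
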