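"""Run configuration: every tunable constant of the pipeline in one
schema-validated, human-readable YAML document.

All defaults are serialised into each run's provenance record, so any
deviation from the standard scenario shows up as a visible diff of the
config file.  The statistics family map is included verbatim so the
family sizes (7 and 16) are auditable.
"""
from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

from .behavior import BehaviorParams, CorruptionParams
from .metrics import OnsetConfig
from .scene import Viewpoint, WallSpec
from .stats import FAMILY_MAP
from .trajectory import AeroParams

__all__ = ["FilterConfig", "SessionConfig", "RunConfig", "config_hash"]


@dataclass(frozen=True)
class FilterConfig:
    cutoff_hz: float = 10.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0 or self.order <= 0:
            raise ValueError("filter settings must be positive")


@dataclass(frozen=True)
class SessionConfig:
    naive_participants: int = 15
    skilled_participants: int = 10
    experimental_repetitions: int = 5
    dummy_repetitions: int = 2

    def __post_init__(self) -> None:
        if self.naive_participants < 0 or self.skilled_participants < 0:
            raise ValueError("participant counts must be non-negative")


def _from_mapping(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 12345
    aero: AeroParams = field(default_factory=AeroParams)
    wall: WallSpec = field(default_factory=WallSpec)
    viewpoint: Viewpoint = field(default_factory=Viewpoint)
    behavior_naive: BehaviorParams = field(default_factory=BehaviorParams)
    # Skilled keepers: shorter latency, quicker hands, less aim noise.
    behavior_skilled: BehaviorParams = field(
        default_factory=lambda: BehaviorParams(
            base_latency_mean=0.21,
            reach_speed=2.2,
            endpoint_noise_sd=0.02,
            curve_bias_gain=0.28,
        )
    )
    corruption: CorruptionParams = field(default_factory=CorruptionParams)
    filter: FilterConfig = field(default_factory=FilterConfig)
    onset: OnsetConfig = field(default_factory=OnsetConfig)
    session: SessionConfig = field(default_factory=SessionConfig)
    family_map: dict = field(default_factory=lambda: dict(FAMILY_MAP))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["viewpoint"]["eye"] = list(self.viewpoint.eye)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        parts = {}
        mapping = {
            "aero": AeroParams,
            "wall": WallSpec,
            "behavior_naive": BehaviorParams,
            "behavior_skilled": BehaviorParams,
            "corruption": CorruptionParams,
            "filter": FilterConfig,
            "onset": OnsetConfig,
            "session": SessionConfig,
        }
        for key, sub_cls in mapping.items():
            if key in data:
                parts[key] = _from_mapping(sub_cls, data.pop(key))
        if "viewpoint" in data:
            eye = tuple(data.pop("viewpoint")["eye"])
            parts["viewpoint"] = Viewpoint(eye)
        if "family_map" in data:
            parts["family_map"] = data.pop("family_map")
        if "seed" in data:
            parts["seed"] = int(data.pop("seed"))
        if data:
            raise ValueError(f"unknown config keys: {sorted(data)}")
        return cls(**parts)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})


def config_hash(config: RunConfig) -> str:
    """Short stable digest of the fully serialised configuration."""
    text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
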