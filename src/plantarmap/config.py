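"""Run configuration: every pipeline tunable in one serializable record."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .registration import DemonsConfig, RigidRegistrationConfig


@dataclass
class RunConfig:
    """All pipeline tunables with their defaults.

    Serialized (YAML/JSON) alongside every run's outputs so that any
    artifact is reproducible from (inputs, resolved config, seed).
    """

    # preprocessing
    target_grid_mm: float = 3.0
    contact_threshold_kpa: float = 5.0
    # registration
    mi_bins: int = 50
    rigid: RigidRegistrationConfig = field(default_factory=RigidRegistrationConfig)
    demons: DemonsConfig = field(default_factory=DemonsConfig)
    # templating
    template_max_iter: int = 10
    template_tol: float = 1e-3
    # statistics
    alpha: float = 0.05
    two_sided: bool = True
    t_variant: str = "crawford"
    variance_divisor: str = "model"
    min_overlap_px: int = 4
    dice_floor: float = 0.85
    # region geometry (fractions of foot length)
    region_heel_end: float = 0.31
    region_midfoot_end: float = 0.55
    region_metatarsal_end: float = 0.81
    region_mt1_width_fraction: float = 0.36
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.rigid, dict):
            self.rigid = RigidRegistrationConfig(**self.rigid)
        if isinstance(self.demons, dict):
            self.demons = DemonsConfig(**self.demons)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
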