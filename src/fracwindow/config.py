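"""Run configuration: one YAML file driving phantom, materials, thresholds,
gait model, solver and the three studies."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .gait import LoadModelParams
from .materials import MaterialTable
from .mechanoreg import HealingThresholds, default_thresholds
from .phantom import PhantomConfig


@dataclass
class GaitConfig:
    """Synthetic-trial conditions for the studies."""

    body_mass_kg: float = 95.0
    effective_load_frac: float = 0.37  # observed ~35 kg peak on a 95 kg patient
    n_steps: int = 30
    velocities_kmh: tuple[float, ...] = (1.0, 1.5, 2.0)
    caps_kg: tuple[float, ...] = (20.0, 35.0, 95.0)
    n_frames: int = 16
    swing_frames: int = 6


@dataclass
class SolverConfig:
    target_edge_mm: float | None = None  # None = mesh at native voxel resolution
    rtol: float = 1e-8


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    materials: MaterialTable = field(default_factory=MaterialTable)
    mechanoregulation: HealingThresholds = field(default_factory=default_thresholds)
    gait: GaitConfig = field(default_factory=GaitConfig)
    load_model: LoadModelParams = field(default_factory=LoadModelParams)
    solver: SolverConfig = field(default_factory=SolverConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["materials"] = self.materials.to_dict()
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def default_config(seed: int = 0) -> RunConfig:
    cfg = RunConfig(seed=seed)
    cfg.phantom.seed = seed
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from YAML; absent sections keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig()
    if "phantom" in raw:
        d = dict(raw["phantom"])
        for key in ("fibula_fracture_levels_mm",):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        cfg.phantom = PhantomConfig(**d)
    if "materials" in raw:
        cfg.materials = MaterialTable.from_dict(raw["materials"])
    if "mechanoregulation" in raw:
        m = raw["mechanoregulation"]
        cfg.mechanoregulation = default_thresholds(
            fibrous_in_window=m.get("fibrous_in_window", True),
            axis_mode=m.get("axis_mode", "strain"),
        )
    if "gait" in raw:
        d = dict(raw["gait"])
        for key in ("velocities_kmh", "caps_kg"):
            if key in d:
                d[key] = tuple(d[key])
        cfg.gait = GaitConfig(**d)
    if "load_model" in raw:
        d = dict(raw["load_model"])
        for key in ("bending_axis", "load_direction"):
            if key in d:
                d[key] = tuple(d[key])
        cfg.load_model = LoadModelParams(**d)
    if "solver" in raw:
        cfg.solver = SolverConfig(**raw["solver"])
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
        cfg.phantom.seed = cfg.seed
    return cfg
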