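"""Validated run configuration: geometry, materials, load, training,
optimization and the single seed all randomness flows from.

Unknown keys anywhere in the document are rejected, so typos fail loudly
before any computation starts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .fem import MaterialParams
from .geometry import DiscGeometryParams
from .model import TrainConfig

__all__ = ["RunConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryBlock(_Strict):
    lateral_radius: float = Field(20.0, gt=0, description="mm")
    ap_radius: float = Field(14.0, gt=0, description="mm")
    height: float = Field(8.0, gt=0, description="mm")
    nucleus_scale: float = Field(0.6, gt=0, lt=1)
    n_radial: int = Field(5, ge=2)
    n_circumferential: int = Field(16, ge=2)
    n_axial: int = Field(4, ge=2)


class ComponentMaterial(_Strict):
    young_modulus: float = Field(gt=0, description="MPa")
    poisson_ratio: float = Field(ge=0, lt=0.5)


class MaterialsBlock(_Strict):
    annulus: ComponentMaterial = ComponentMaterial(young_modulus=3.4, poisson_ratio=0.45)
    nucleus: ComponentMaterial = ComponentMaterial(young_modulus=1.0, poisson_ratio=0.49)


class LoadBlock(_Strict):
    uiv_fraction: float = Field(0.5, gt=0, le=1)
    #: optional per-UIV-level overrides, e.g. {"T2": 0.65, "T10": 0.45}
    uiv_fraction_by_level: dict[str, float] = Field(default_factory=dict)
    gravity: float = Field(9.81, gt=0, description="m/s^2")

    def fraction_for(self, level: str | None) -> float:
        if level is not None and level in self.uiv_fraction_by_level:
            return self.uiv_fraction_by_level[level]
        return self.uiv_fraction


class TrainingBlock(_Strict):
    hidden_width: int = Field(8, ge=1)
    learning_rate: float = Field(0.01, gt=0)
    adam_beta1: float = Field(0.9, gt=0, lt=1)
    adam_beta2: float = Field(0.999, gt=0, lt=1)
    adam_epsilon: float = Field(1e-8, gt=0)
    epochs: int = Field(2000, ge=1)
    init_scale: float = Field(1.0, gt=0)


class OptimizationBlock(_Strict):
    alpha_lo: float = Field(0.0, ge=0, lt=90)
    alpha_hi: float = Field(45.0, gt=0, lt=90)
    risk_tolerance: float = Field(1e-3, gt=0)
    grid_step_deg: float = Field(0.1, gt=0)


class RunConfig(_Strict):
    geometry: GeometryBlock = GeometryBlock()
    materials: MaterialsBlock = MaterialsBlock()
    load: LoadBlock = LoadBlock()
    training: TrainingBlock = TrainingBlock()
    optimization: OptimizationBlock = OptimizationBlock()
    seed: int = Field(0, ge=0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(doc)

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    # -- adapters to the library dataclasses ------------------------------

    def geometry_params(self) -> DiscGeometryParams:
        return DiscGeometryParams(**self.geometry.model_dump())

    def material_params(self) -> MaterialParams:
        return MaterialParams(
            young_modulus={"annulus": self.materials.annulus.young_modulus,
                           "nucleus": self.materials.nucleus.young_modulus},
            poisson_ratio={"annulus": self.materials.annulus.poisson_ratio,
                           "nucleus": self.materials.nucleus.poisson_ratio},
        )

    def train_config(self, seed: int | None = None) -> TrainConfig:
        return TrainConfig(seed=self.seed if seed is None else seed,
                           **self.training.model_dump())
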