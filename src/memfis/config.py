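"""Validated run configurations for the command-line interface.

A run is described by a YAML (or JSON) document with three blocks: the run
``kind``, the ``model`` constants, the ``grid``, and a kind-specific block.
Unknown keys are rejected so typos fail loudly before any computation.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .geometry import Grid
from .params import ModelParams

__all__ = ["RunConfig", "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelBlock(_Strict):
    chiN: float = 30.0
    f: float = 0.8
    solvent_ratio: float = 0.1
    mu: float = 0.0
    ds: float = 0.01

    @field_validator("f")
    @classmethod
    def _f_in_unit_interval(cls, v):
        if not 0.0 < v < 1.0:
            raise ValueError(f"f must lie in (0, 1), got {v}")
        return v

    @field_validator("chiN", "solvent_ratio", "ds")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive, got {v}")
        return v

    def to_params(self) -> ModelParams:
        return ModelParams(chiN=self.chiN, f=self.f,
                           solvent_ratio=self.solvent_ratio, mu=self.mu,
                           ds=self.ds)


class GridBlock(_Strict):
    kind: Literal["planar1d", "radial1d", "axisym2d", "cart3d"] = "planar1d"
    extents: list[float] = Field(default_factory=lambda: [16.0])
    dx: float = 0.05
    boundary: Optional[list[str]] = None

    def to_grid(self) -> Grid:
        shape = tuple(round(e / self.dx) for e in self.extents)
        spacings = (self.dx,) * len(shape)
        boundary = tuple(self.boundary) if self.boundary else ()
        return Grid(self.kind, shape, spacings, boundary)


class SolverBlock(_Strict):
    tol: float = 1e-6
    max_iter: int = 4000
    mixing: float = 0.02
    warmup: int = 100


class ConvergeBlock(_Strict):
    seed_kind: str = "planar_bilayer"
    seed_geometry: dict = Field(default_factory=dict)
    lipid_mass: Optional[float] = None
    seed_mu: Optional[float] = None


class SweepBlock(_Strict):
    masses: list[float] = Field(
        default_factory=lambda: [0.9, 1.0, 1.1, 1.2, 1.3, 1.4])


class TubeBlock(_Strict):
    sigma_phys_dyn_cm: Optional[float] = None
    sigma_model: Optional[float] = None
    n_bilayers: int = 1
    gap: float = 1.0
    radius_max: float = 12.0


class MfepBlock(_Strict):
    landscape: Literal["two_well", "scft"] = "two_well"
    n_nodes: int = 20
    n_outer: int = 200
    inner_steps: int = 10
    tol: float = 1e-8
    start_kind: Optional[str] = None
    end_kind: Optional[str] = None
    start_geometry: dict = Field(default_factory=dict)
    end_geometry: dict = Field(default_factory=dict)


class FluorBlock(_Strict):
    input_csv: Optional[str] = None
    D: float = 100.0
    radius_um: float = 0.02
    n_tubes: int = 200
    dm_fraction: float = 0.5
    noise_sd: float = 0.1
    seed: int = 0


class RunConfig(_Strict):
    kind: Literal["converge", "tension_sweep", "tube", "dm_tube", "mfep",
                  "fluor"]
    model: ModelBlock = Field(default_factory=ModelBlock)
    grid: GridBlock = Field(default_factory=GridBlock)
    solver: SolverBlock = Field(default_factory=SolverBlock)
    converge: Optional[ConvergeBlock] = None
    sweep: Optional[SweepBlock] = None
    tube: Optional[TubeBlock] = None
    mfep: Optional[MfepBlock] = None
    fluor: Optional[FluorBlock] = None
    seed: int = 0


def load_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of a config, embedded in every output artifact."""
    blob = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
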