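"""Structured run configuration: YAML schema, validation, presets.

One dialect only (YAML), validated by a versioned pydantic schema that
rejects unknown keys with field-path error messages.  Presets named after
the experiments they reproduce ship inside the package.
"""

from __future__ import annotations

from importlib import resources
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .engine import BC_VARIANTS, EngineConfig
from .geometry import make_generating_curve
from .kinematics import GrowthIncrementSpec
from .mechanics import MaterialModel, SolverSettings

__all__ = ["RunConfig", "read_config", "load_preset", "preset_names", "build_engine_config"]


class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["line", "arc", "circle", "varying"] = "line"
    length: Optional[float] = 10.0          # line/varying; arc extent for arc
    radius: Optional[float] = None          # arc/circle
    kappa_xi2: Optional[list[float]] = None
    kappa_values: Optional[list[float]] = None
    bend: Literal["in_surface", "out_of_surface"] = "in_surface"
    n_elem_s2: int = Field(48, ge=4)
    layers: int = Field(1, ge=1, le=4)
    basis_order: Literal[1, 2] = 2
    h: float = Field(0.35, gt=0)

    @model_validator(mode="after")
    def _check(self):
        if self.kind in ("arc", "circle") and (self.radius is None or self.radius <= 0):
            raise ValueError("geometry.radius must be positive for arc/circle")
        if self.kind in ("line", "varying", "arc") and (
            self.length is None or self.length <= 0
        ):
            raise ValueError("geometry.length must be positive")
        if self.kind == "varying" and (self.kappa_xi2 is None or self.kappa_values is None):
            raise ValueError("geometry.kappa_xi2/kappa_values required for 'varying'")
        return self


class IncrementConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    delta_s: float = Field(ge=0)
    delta_g: float = 0.0
    rows: int = Field(4, ge=1)
    profile_xi1: Optional[list[list[float]]] = None  # [[xi1_frac, eps2], ...]


class GrowthConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    increments: list[IncrementConfig] = Field(min_length=1)


class MaterialConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mu: float = Field(1.0, gt=0)
    lam: float = Field(2.0, ge=0)


class BCConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    variant: Literal[tuple(BC_VARIANTS)] = "trailing_fixed_rest_free"


class SolverConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    load_steps: int = Field(20, ge=1)
    newton_tol: float = Field(1e-8, gt=0)
    max_newton_iter: int = Field(30, ge=1)
    imperfection_amplitude: float = Field(1e-3, ge=0)
    imperfection_seed: int = 0
    quadrature_order: Optional[int] = None


class SweepConfig(BaseModel):
    """Parameter families for experiment drivers that rerun the base config."""

    model_config = ConfigDict(extra="forbid")

    delta_s_multipliers: Optional[list[float]] = None
    delta_g_multipliers: Optional[list[float]] = None
    delta_g_step: Optional[float] = None       # upward-sweep resolution
    delta_g_max: Optional[float] = None        # upward-sweep bound
    detection_amplitude_h: float = 0.02        # bifurcation floor, units of h


class OutputConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    write_vtu: bool = True
    check_self_intersection: bool = False


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    schema_version: int = 1
    preset_name: Optional[str] = None
    geometry: GeometryConfig = GeometryConfig()
    growth: GrowthConfig
    material: MaterialConfig = MaterialConfig()
    bcs: BCConfig = BCConfig()
    solver: SolverConfig = SolverConfig()
    output: OutputConfig = OutputConfig()
    sweep: Optional[SweepConfig] = None
    calcification_mode: Literal["full", "remark2_elastic_tail"] = "full"
    elastic_tail: int = Field(0, ge=0)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


def read_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as f:
        data = yaml.safe_load(f)
    return RunConfig.model_validate(data)


def preset_names() -> list[str]:
    pkg = resources.files("shellgrow") / "presets"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> RunConfig:
    pkg = resources.files("shellgrow") / "presets" / f"{name}.yaml"
    if not pkg.is_file():
        raise FileNotFoundError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        )
    cfg = RunConfig.model_validate(yaml.safe_load(pkg.read_text()))
    cfg.preset_name = name
    return cfg


def build_engine_config(cfg: RunConfig) -> EngineConfig:
    """Materialize the validated config into engine inputs."""
    g = cfg.geometry
    n_samples = g.n_elem_s2 + 1
    if g.kind == "line":
        curve = make_generating_curve("line", g.length, n_samples=n_samples)
    elif g.kind == "arc":
        curve = make_generating_curve(
            "arc", g.radius, {"arc_length": g.length}, n_samples=n_samples
        )
    elif g.kind == "circle":
        curve = make_generating_curve("circle", g.radius, n_samples=n_samples)
    else:
        curve = make_generating_curve(
            "varying",
            g.length,
            {"xi2": g.kappa_xi2, "kappa": g.kappa_values, "bend": g.bend},
            n_samples=n_samples,
        )
    increments = [
        GrowthIncrementSpec(
            delta_s=inc.delta_s,
            eps2=inc.delta_g,
            dt=1.0,
            n_rows=inc.rows,
            profile_xi1=tuple(map(tuple, inc.profile_xi1)) if inc.profile_xi1 else None,
        )
        for inc in cfg.growth.increments
    ]
    return EngineConfig(
        curve=curve,
        material=MaterialModel(mu=cfg.material.mu, lam=cfg.material.lam),
        solver=SolverSettings(
            load_steps=cfg.solver.load_steps,
            newton_tol=cfg.solver.newton_tol,
            max_newton_iter=cfg.solver.max_newton_iter,
            imperfection_amplitude=cfg.solver.imperfection_amplitude,
            imperfection_seed=cfg.solver.imperfection_seed,
            quadrature_order=cfg.solver.quadrature_order,
        ),
        increments=increments,
        n_elem_s2=g.n_elem_s2,
        layers=g.layers,
        basis_order=g.basis_order,
        h=g.h,
        bc_variant=cfg.bcs.variant,
        calcification_mode=cfg.calcification_mode,
        elastic_tail=cfg.elastic_tail,
        check_self_intersection=cfg.output.check_self_intersection,
    )
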