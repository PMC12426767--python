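"""Validated experiment configuration (YAML-friendly, strict schema)."""

from __future__ import annotations

from typing import Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = ["RunConfig", "FluidConfig", "load_config"]

_ALLOWED_WSS = {"p1", "dg1", "dg0", "bflux-p1", "bflux-p2"}


class FluidConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dynamic_viscosity: Optional[float] = None
    kinematic_viscosity: Optional[float] = None
    density: float = 1.0
    density_scaled: bool = True


class StabilizationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    gamma_p: Optional[float] = None
    gamma_v: Optional[float] = None
    alpha_i: float = 1e-3
    alpha_v: float = 1e-3
    alpha_p: float = 1.0


class RunConfig(BaseModel):
    """One reproducible experiment run.

    ``levels`` are elements-per-side for the square benchmark and edge
    lengths (meters) for the cylinder; external meshes take a path plus a
    region-name map."""

    model_config = ConfigDict(extra="forbid")

    experiment: Literal["stokes2d", "poiseuille", "external_mesh"]
    element_pair: Literal["p1p1", "p2p1"] = "p2p1"
    enforcement: Optional[Literal["strong", "nitsche"]] = None
    nitsche_beta: float = 10.0
    stabilization: StabilizationConfig = StabilizationConfig()
    mesh_family: Literal["uniform", "boundary_layer"] = "uniform"
    levels: Optional[Sequence[float]] = None
    mesh_path: Optional[str] = None
    region_names_path: Optional[str] = None
    dome_tag: Optional[int] = None
    parent_tag: Optional[int] = None
    inlet_tag: Optional[int] = None
    outlet_tags: Sequence[int] = ()
    wall_tags: Sequence[int] = ()
    mean_inflow_velocity: float = 0.5
    fluid: Optional[FluidConfig] = None
    wss_methods: Optional[Sequence[str]] = None
    solver: Literal["stokes", "navier_stokes"] = "stokes"
    output_dir: str = "results"
    random_seed: int = 0

    @field_validator("wss_methods")
    @classmethod
    def _known_methods(cls, v):
        if v is None:
            return v
        bad = set(m.lower() for m in v) - _ALLOWED_WSS
        if bad:
            raise ValueError(f"unknown WSS methods {sorted(bad)}; "
                             f"allowed: {sorted(_ALLOWED_WSS)}")
        return [m.lower() for m in v]

    @model_validator(mode="after")
    def _cross_checks(self):
        if self.element_pair == "p1p1":
            if self.enforcement == "strong":
                raise ValueError("p1p1 requires Nitsche (weak) enforcement")
            if self.wss_methods and "bflux-p2" in self.wss_methods:
                raise ValueError(
                    "boundary-flux space P2 exceeds the velocity degree of "
                    "the p1p1 element pair"
                )
        if self.experiment == "external_mesh":
            if not self.mesh_path:
                raise ValueError("external_mesh experiments need mesh_path")
            if self.fluid is None or (
                self.fluid.dynamic_viscosity is None
                and self.fluid.kinematic_viscosity is None
            ):
                raise ValueError(
                    "external meshes need explicit fluid properties "
                    "(they are not implied by the geometry)"
                )
        return self

    @property
    def resolved_enforcement(self) -> str:
        if self.enforcement is not None:
            return self.enforcement
        return "nitsche" if self.element_pair == "p1p1" else "strong"


def load_config(path: str) -> RunConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)
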