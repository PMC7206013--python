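"""Validated pipeline configuration.

One YAML file drives every stage.  Validation happens before anything runs:
unknown keys are rejected, cross-field constraints are enforced by the same
dataclass checks the library applies, and the seed is mandatory because
simulation, half-split CC1/2 and the rejection loop are all seeded.  Reports
embed a hash of the validated config for provenance.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .assembly import AssemblyConfig, RejectionConfig
from .scaling import ScalingConfig
from .simulate import SimulationConfig
from .symmetry import UnitCell

__all__ = ["PipelineSettings", "load_pipeline_config", "config_hash", "ConfigError"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationSettings(_Strict):
    n_crystals: int = 132
    cell: list[float] = Field(default=[50.0, 60.0, 70.0, 90.0, 90.0, 90.0], min_length=6, max_length=6)
    cell_jitter_sigma: float = 0.05
    d_min: float = 3.0
    wilson_Sigma0: float = 1000.0
    wilson_B: float = 15.0
    scale_range: tuple[float, float] = (0.5, 2.0)
    B_range: tuple[float, float] = (0.0, 20.0)
    wedge_width: float = 20.0
    frames_per_wedge: int = 20
    noise_floor: float = 25.0
    noise_scale: float = 1.0
    n_outliers: int = 0
    outlier_corr: float = 0.5
    outlier_cell_shift: float = 0.0
    anom_fraction: float = 0.0


class ClusteringSettings(_Strict):
    max_groups: int = 20
    reject_z: float = 3.0
    angle_weight: float = 1.0


class ScalingSettings(_Strict):
    min_common: int = 20
    max_iter: int = 100
    tol: float = 1e-6
    per_frame: bool = False
    n_shells: int = 10


class RejectionSettings(_Strict):
    objective: Literal["cc_half", "cc_anom"] = "cc_half"
    tol: float = 0.001
    min_crystals: int = 3
    min_frames_per_crystal: int = 2


class PipelineSettings(_Strict):
    schema_version: int = 1
    seed: int
    space_group: str = "P212121"
    friedel_merged: bool = True
    min_completeness: float = 0.90
    simulation: SimulationSettings = Field(default_factory=SimulationSettings)
    clustering: ClusteringSettings = Field(default_factory=ClusteringSettings)
    scaling: ScalingSettings = Field(default_factory=ScalingSettings)
    rejection: RejectionSettings = Field(default_factory=RejectionSettings)

    def simulation_config(self) -> SimulationConfig:
        s = self.simulation
        return SimulationConfig(
            n_crystals=s.n_crystals,
            cell0=UnitCell(*s.cell),
            cell_jitter_sigma=s.cell_jitter_sigma,
            space_group=self.space_group,
            d_min=s.d_min,
            wilson_Sigma0=s.wilson_Sigma0,
            wilson_B=s.wilson_B,
            scale_range=tuple(s.scale_range),
            B_range=tuple(s.B_range),
            wedge_width=s.wedge_width,
            frames_per_wedge=s.frames_per_wedge,
            noise_floor=s.noise_floor,
            noise_scale=s.noise_scale,
            n_outliers=s.n_outliers,
            outlier_corr=s.outlier_corr,
            outlier_cell_shift=s.outlier_cell_shift,
            anom_fraction=s.anom_fraction,
            friedel_merged=self.friedel_merged,
            seed=self.seed,
        )

    def scaling_config(self) -> ScalingConfig:
        s = self.scaling
        return ScalingConfig(
            min_common=s.min_common,
            max_iter=s.max_iter,
            tol=s.tol,
            per_frame=s.per_frame,
            n_shells=s.n_shells,
            split_seed=self.seed,
        )

    def rejection_config(self) -> RejectionConfig:
        r = self.rejection
        return RejectionConfig(
            objective=r.objective,
            tol=r.tol,
            min_crystals=r.min_crystals,
            min_frames_per_crystal=r.min_frames_per_crystal,
            split_seed=self.seed,
            scaling=self.scaling_config(),
        )

    def assembly_config(self) -> AssemblyConfig:
        c = self.clustering
        return AssemblyConfig(
            max_groups=c.max_groups,
            reject_z=c.reject_z,
            angle_weight=c.angle_weight,
            min_completeness=self.min_completeness,
            n_shells=self.scaling.n_shells,
            split_seed=self.seed,
            scaling=self.scaling_config(),
            rejection=self.rejection_config(),
        )


def load_pipeline_config(path, seed_override: int | None = None) -> PipelineSettings:
    """Load and validate a YAML pipeline config; errors name the field."""
    with open(path, "r", encoding="ascii") as fh:
        raw = yaml.safe_load(fh) or {}
    if seed_override is not None:
        raw["seed"] = seed_override
    try:
        settings = PipelineSettings(**raw)
    except ValidationError as exc:
        fields = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in exc.errors()
        )
        raise ConfigError(f"invalid pipeline config {path}: {fields}") from exc
    # run the library-level validators too (cross-field constraints)
    try:
        settings.simulation_config()
    except ValueError as exc:
        raise ConfigError(f"invalid pipeline config {path}: {exc}") from exc
    return settings


def config_hash(settings: PipelineSettings) -> str:
    payload = json.dumps(settings.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
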