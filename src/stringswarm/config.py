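"""Run configuration: schema-validated YAML describing a full toy study.

Validation happens before any computation; unknown keys are errors (nothing
is silently ignored) and all violations are reported together.  Defaults
mirror the production protocol constants: 305 string iterations with 16–32
swarm trajectories per point, 24 walkers × 8 iterations of adaptive state
sampling, 1000 posterior transition matrices, 50 RBMs with a 0.33 importance
threshold, and a base restraint force constant of 3366.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config"]


class ConfigError(ValueError):
    """Carries every violation found in a config file, not just the first."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {v}" for v in violations))


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PotentialConfig(_Strict):
    name: str
    params: dict[str, Any] = Field(default_factory=dict)


class EngineConfig(_Strict):
    timestep: float = Field(1e-3, gt=0)
    diffusion_coefficient: float = Field(1.0, gt=0)
    kT: float = Field(1.0, gt=0)


class CVConfig(_Strict):
    bounds: list[tuple[float, float]]
    importance: list[float] | None = None

    @model_validator(mode="after")
    def _check(self):
        for j, (lo, hi) in enumerate(self.bounds):
            if not lo < hi:
                raise ValueError(f"cv bounds[{j}]: min must be < max")
        if self.importance is not None:
            if len(self.importance) != len(self.bounds):
                raise ValueError("importance length must match bounds length")
            if any(not 0 < w <= 1 for w in self.importance):
                raise ValueError("importance weights must lie in (0, 1]")
        return self


class CVSelectionSettings(_Strict):
    n_hidden: int = Field(2, ge=1)
    n_models: int = Field(50, ge=1)
    importance_threshold: float = Field(0.33, ge=0, le=1)
    distance_window: tuple[float, float] = (6.0, 8.0)

    @model_validator(mode="after")
    def _check(self):
        if not self.distance_window[0] < self.distance_window[1]:
            raise ValueError("distance_window: low must be < high")
        return self


class StringSettings(_Strict):
    n_points: int = Field(20, ge=3)
    swarm_min: int = Field(16, ge=1)
    swarm_max: int = Field(32, ge=1)
    swarm_len: int = Field(20, ge=0)
    restrained_len: int = Field(30, ge=0)
    max_iterations: int = Field(305, ge=1)
    averaging_window: int = Field(60, ge=1)
    base_force_constant: float = 3366.0
    drift_tolerance: float = Field(default=float("inf"))
    convergence_tolerance: float = Field(1e-2, gt=0)
    fixed_endpoints: bool = True
    smoothing: float = Field(0.0, ge=0, lt=1)

    @model_validator(mode="after")
    def _check(self):
        if self.swarm_min > self.swarm_max:
            raise ValueError("swarm_min must not exceed swarm_max")
        if self.averaging_window > self.max_iterations:
            raise ValueError("averaging_window must not exceed max_iterations")
        if self.base_force_constant < 0:
            raise ValueError("base_force_constant must be >= 0")
        return self


class StateSamplerSettings(_Strict):
    iterations: int = Field(8, ge=1)
    total: int = Field(24, ge=1)
    traj_len: int = Field(150, ge=1)
    convergence_fraction: float = Field(0.01, gt=0)


class GridConfig(_Strict):
    mins: list[float]
    maxs: list[float]
    n_bins: list[int]

    @model_validator(mode="after")
    def _check(self):
        if not len(self.mins) == len(self.maxs) == len(self.n_bins):
            raise ValueError("grid mins, maxs and n_bins must have equal length")
        for j, (lo, hi, nb) in enumerate(zip(self.mins, self.maxs, self.n_bins)):
            if not lo < hi:
                raise ValueError(f"grid variable {j}: min must be < max")
            if nb < 2:
                raise ValueError(f"grid variable {j}: need at least 2 bins")
        return self


class BasinConfig(_Strict):
    name: str
    lo: list[float]
    hi: list[float]


class FESSettings(_Strict):
    production_rounds: int = Field(100, ge=1)
    n_posterior_samples: int = Field(1000, ge=1)
    pseudo_count: float | None = None


class RunConfig(_Strict):
    """Everything a demo run needs; every random operation derives its stream
    from ``seed``."""

    potential: PotentialConfig
    engine: EngineConfig = Field(default_factory=EngineConfig)
    cv: CVConfig
    cv_selection: CVSelectionSettings = Field(default_factory=CVSelectionSettings)
    string: StringSettings = Field(default_factory=StringSettings)
    state_sampler: StateSamplerSettings = Field(default_factory=StateSamplerSettings)
    grid: GridConfig
    basins: list[BasinConfig] = Field(default_factory=list)
    anchors: list[list[float]] | None = None
    string_iterations: int | None = None
    fes: FESSettings = Field(default_factory=FESSettings)
    seed: int = 0
    output_dir: str = "stringswarm_run"


def _format_errors(exc: ValidationError) -> list[str]:
    out = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        out.append(f"{loc}: {err['msg']}")
    return out


def validate_config(source) -> RunConfig:
    """Load and validate a YAML config file (or pre-parsed mapping); raises
    :class:`ConfigError` listing all violations."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = source
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_errors(exc)) from None


load_config = validate_config
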