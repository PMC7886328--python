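"""Overdamped Brownian-dynamics engine.

The propagator is the Euler–Maruyama discretization of overdamped Langevin
dynamics,

    x(t+Δt) = x(t) − (D·Δt/kT)·∇U(x) + sqrt(2·D·Δt)·ξ,   ξ ~ N(0, I),

which is ergodic for the Boltzmann density exp(−U/kT)/Z on any confining
potential.  It stands in for the molecular-dynamics propagator behind swarm
and equilibration trajectories.  Randomness is organised as one counter-based
substream per (seed, *key) so that results are independent of execution
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cv import CVSet
from .potentials import AnalyticPotential

__all__ = [
    "EngineParams",
    "PropagationError",
    "substream_rng",
    "brownian_step",
    "propagate",
    "sample_restrained",
]


class PropagationError(RuntimeError):
    """Raised when the dynamics produces a non-finite force or coordinate."""


@dataclass(frozen=True)
class EngineParams:
    """Reduced-unit integrator parameters.

    timestep and diffusion_coefficient set the mobility D·Δt/kT; kT is the
    thermal energy unit (1 by default, matching the potentials' kT units).
    """

    timestep: float = 1e-3
    diffusion_coefficient: float = 1.0
    kT: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion_coefficient must be > 0")
        if self.kT <= 0:
            raise ValueError("kT must be > 0")

    @property
    def mobility(self) -> float:
        return self.diffusion_coefficient * self.timestep / self.kT

    @property
    def noise_scale(self) -> float:
        return float(np.sqrt(2.0 * self.diffusion_coefficient * self.timestep))


def substream_rng(seed: int, *key: int) -> np.random.Generator:
    """Independent, reproducible random substream for a (seed, key...) tuple."""
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


def _check_finite(g: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(g)):
        bad = np.argwhere(~np.isfinite(np.atleast_2d(g)))
        walker, coord = bad[0]
        raise PropagationError(
            f"non-finite {what} at walker {walker}, coordinate {coord}"
        )


def brownian_step(
    state: np.ndarray,
    potential: AnalyticPotential,
    params: EngineParams,
    rng: np.random.Generator | None = None,
    noise: np.ndarray | None = None,
    extra_force=None,
) -> np.ndarray:
    """One Euler–Maruyama step.  ``state`` may be a point (d,) or batch (n, d).

    ``noise`` overrides the random draw (tests use this to force zero noise);
    ``extra_force`` is an optional callable x → force added to −∇U (restraints).
    """
    x = np.asarray(state, dtype=float)
    g = potential.gradient(x)
    _check_finite(g, "gradient")
    force = -g
    if extra_force is not None:
        force = force + extra_force(x)
    if noise is None:
        if rng is None:
            rng = substream_rng(params.seed)
        noise = rng.standard_normal(x.shape)
    new = x + params.mobility * force + params.noise_scale * np.asarray(noise)
    _check_finite(new, "coordinate")
    return new


def propagate(
    state: np.ndarray,
    potential: AnalyticPotential,
    params: EngineParams,
    n_steps: int,
    rng: np.random.Generator,
    extra_force=None,
    return_trajectory: bool = False,
) -> np.ndarray:
    """Propagate a point or batch for ``n_steps``; returns the final state, or
    the full trajectory of shape (n_steps+1, ...) when requested."""
    x = np.asarray(state, dtype=float).copy()
    traj = [x.copy()] if return_trajectory else None
    for _ in range(int(n_steps)):
        x = brownian_step(x, potential, params, rng=rng, extra_force=extra_force)
        if return_trajectory:
            traj.append(x.copy())
    return np.asarray(traj) if return_trajectory else x


def restraint_force(cv_set: CVSet, anchor_weighted: np.ndarray, force_constants: np.ndarray):
    """Force of the harmonic restraint ½ Σ_j k_j (s̃_j(x) − a_j)² for identity
    CVs, where s̃ is the weighted scaled CV map.  ``anchor_weighted`` may be a
    single anchor (d,) or one anchor per walker (n, d)."""
    k = np.atleast_1d(np.asarray(force_constants, dtype=float))
    if np.any(k < 0):
        raise ValueError("restraint force constants must be >= 0")
    jac = cv_set.jacobian_diag

    def force(x):
        s = cv_set.to_weighted(x)
        return -k * (s - anchor_weighted) * jac

    return force


def sample_restrained(
    potential: AnalyticPotential,
    cv_set: CVSet,
    anchor: np.ndarray,
    force_constants,
    n_steps: int,
    params: EngineParams,
    x0: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    return_trajectory: bool = False,
):
    """Restrained equilibration: propagate under U + harmonic restraint to the
    anchor (given in weighted scaled CV space); returns the final state (the
    swarm launch point) or, on request, the full restrained trajectory.

    Anchors more than 10% outside the scaled bounds trigger a warning only.
    """
    anchor = np.asarray(anchor, dtype=float)
    scaled = anchor / cv_set.importance
    if np.any(scaled < -0.1) or np.any(scaled > 1.1):
        import warnings

        warnings.warn(
            f"restraint anchor {anchor} lies more than 10% outside the scaled CV bounds",
            stacklevel=2,
        )
    if x0 is None:
        x0 = cv_set.from_weighted(anchor)
    if rng is None:
        rng = substream_rng(params.seed, 0)
    force = restraint_force(cv_set, anchor, force_constants)
    return propagate(
        x0, potential, params, n_steps, rng, extra_force=force,
        return_trajectory=return_trajectory,
    )
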