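"""Kinetically-trapped state sampling.

A fixed-size ensemble of walkers is launched from a single configuration and
iteratively reseeded: after each propagation round, the ensemble center c is
the mean of the walker endpoints in weighted CV space, the spread d is the
mean endpoint-to-center distance, each walker gets weight
w_i = exp(−(|x_i − c|/d)²), and the next round extends n_i ∝ w_i/Σw_j copies
of each walker, keeping the total fixed.  Only walkers near the center are
extended, so the ensemble contracts onto — and then diffuses around — the
most stabilized state kinetically accessible from the start, without ever
being forced across barriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cv import CVSet
from .engine import EngineParams, propagate, substream_rng
from .potentials import AnalyticPotential

__all__ = [
    "IterationStats",
    "WalkerEnsemble",
    "center_and_spread",
    "walker_weights",
    "allocate_copies",
    "run_state_sampling",
    "split_thirds",
    "accumulated_time_us",
]


@dataclass
class IterationStats:
    """Per-iteration reseeding statistics: center c, spread d, weights w_i and
    integer allocation n_i (Σ n_i = total)."""

    iteration: int
    center: np.ndarray
    spread: float
    weights: np.ndarray
    allocation: np.ndarray
    center_shift: float = np.nan
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "iteration": self.iteration,
            "center": np.asarray(self.center).tolist(),
            "spread": float(self.spread),
            "weights": np.asarray(self.weights).tolist(),
            "allocation": np.asarray(self.allocation).tolist(),
            "center_shift": float(self.center_shift),
            "degenerate": self.degenerate,
        }


@dataclass
class WalkerEnsemble:
    """Endpoints (weighted CV space) and configurations of the walker set."""

    endpoints: np.ndarray
    x_states: np.ndarray
    total: int = 24
    iteration: int = 0
    stats: list[IterationStats] = field(default_factory=list)

    def __post_init__(self):
        self.endpoints = np.atleast_2d(np.asarray(self.endpoints, dtype=float))
        if len(self.endpoints) != self.total:
            raise ValueError(f"expected {self.total} walkers, got {len(self.endpoints)}")


def center_and_spread(endpoints) -> tuple[np.ndarray, float]:
    """Center c = mean endpoint; spread d = mean Euclidean distance to c
    (distances live in the weighted CV metric).  d = 0 for identical
    endpoints is flagged by the caller's degenerate-weight rule."""
    x = np.atleast_2d(np.asarray(endpoints, dtype=float))
    if len(x) < 2:
        raise ValueError("need at least 2 endpoints")
    c = x.mean(axis=0)
    d = float(np.mean(np.linalg.norm(x - c, axis=1)))
    return c, d


def walker_weights(endpoints, center, spread) -> np.ndarray:
    """w_i = exp(−(|x_i − c|/d)²), each in (0, 1].  For degenerate d = 0 all
    weights are 1 (uniform reseeding)."""
    x = np.atleast_2d(np.asarray(endpoints, dtype=float))
    if spread <= 0:
        return np.ones(len(x))
    r = np.linalg.norm(x - np.asarray(center, dtype=float), axis=1)
    return np.exp(-((r / spread) ** 2))


def allocate_copies(weights, total: int) -> np.ndarray:
    """Integer allocation n_i ∝ w_i/Σw_j with Σ n_i = total, by
    largest-remainder (Hamilton) rounding; ties broken by lower walker index."""
    if total < 1:
        raise ValueError("total must be >= 1")
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("sum of weights must be positive")
    quota = total * w / w.sum()
    n = np.floor(quota).astype(int)
    remainder = quota - n
    short = total - int(n.sum())
    if short > 0:
        # stable: larger remainder first, lower index wins ties
        order = np.lexsort((np.arange(len(w)), -remainder))
        n[order[:short]] += 1
    return n


def accumulated_time_us(total: int, traj_ns: float, iterations: int) -> float:
    """Bookkeeping of accumulated sampling time: walkers × trajectory length ×
    iterations, reported in µs."""
    if total < 0 or traj_ns < 0 or iterations < 0:
        raise ValueError("inputs must be non-negative")
    return total * traj_ns * iterations / 1000.0


def run_state_sampling(
    potential: AnalyticPotential,
    cv_set: CVSet,
    start,
    params: EngineParams,
    iterations: int = 8,
    total: int = 24,
    traj_len: int = 150,
    convergence_fraction: float = 0.01,
) -> WalkerEnsemble:
    """Run the adaptive reseeding protocol from a single start configuration
    (physical coordinates).

    Records per-iteration :class:`IterationStats` including the center shift
    |c_t − c_{t−1}|; the run is considered converged when the shift drops
    below ``convergence_fraction``·d (reported, not enforced).
    """
    start = np.asarray(start, dtype=float)
    X = np.tile(start, (total, 1))
    ensemble = WalkerEnsemble(
        endpoints=cv_set.to_weighted(X), x_states=X.copy(), total=total
    )
    prev_center = None
    for t in range(iterations):
        rng = substream_rng(params.seed, 7, t)
        X = propagate(ensemble.x_states, potential, params, traj_len, rng)
        if not np.all(np.isfinite(X)):
            raise RuntimeError(f"all-walker propagation failure at iteration {t}")
        endpoints = cv_set.to_weighted(X)
        c, d = center_and_spread(endpoints)
        w = walker_weights(endpoints, c, d)
        n = allocate_copies(w, total)
        shift = np.nan if prev_center is None else float(np.linalg.norm(c - prev_center))
        ensemble.stats.append(
            IterationStats(
                iteration=t,
                center=c,
                spread=d,
                weights=w,
                allocation=n,
                center_shift=shift,
                degenerate=d == 0.0,
            )
        )
        prev_center = c
        # reseed: extend n_i copies of each walker's endpoint configuration
        X = np.repeat(X, n, axis=0)
        ensemble = WalkerEnsemble(
            endpoints=cv_set.to_weighted(X),
            x_states=X,
            total=total,
            iteration=t + 1,
            stats=ensemble.stats,
        )
    return ensemble


def split_thirds(ensemble: WalkerEnsemble, seed: int = 0) -> list[np.ndarray]:
    """Random disjoint partition of the walker endpoints into three sub-groups
    (sizes differing by at most 1) for cross-validation; deterministic under
    ``seed``."""
    n = len(ensemble.endpoints)
    if n < 3:
        raise ValueError("need at least 3 walkers to split into thirds")
    rng = substream_rng(seed, 3)
    perm = rng.permutation(n)
    sizes = [n // 3 + (1 if r < n % 3 else 0) for r in range(3)]
    out, at = [], 0
    for s in sizes:
        out.append(ensemble.endpoints[perm[at : at + s]])
        at += s
    return out
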