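"""String method with swarms of trajectories.

A *string* is an ordered set of points in weighted scaled CV space connecting
two states.  Each iteration (i) re-equilibrates a restrained walker at every
point, (ii) launches a swarm of short unbiased trajectories from the
equilibrated configuration, (iii) displaces each point by the swarm's mean
displacement (the *drift*, proportional to minus the free-energy gradient
times a mobility), and (iv) reparametrizes the string to equal arc length in
the weighted metric.  The string relaxes toward the most probable transition
path; convergence is assessed on strings averaged over a trailing window,
since individual iterations diffuse around the equilibrium path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .cv import CVSet
from .engine import EngineParams, PropagationError, propagate, restraint_force, substream_rng
from .potentials import AnalyticPotential

__all__ = [
    "StringConfig",
    "StringPath",
    "SwarmRecord",
    "initialize_path",
    "reparametrize",
    "run_swarm",
    "update_string",
    "check_convergence",
    "simulation_budget",
    "StringSampler",
]


@dataclass
class StringConfig:
    """Protocol constants of the string/swarm iteration.

    Defaults mirror the production protocol: swarms of 16–32 trajectories,
    305 iterations with strings averaged over the trailing 60, and a base
    restraint force constant of 3366 (energy/length², scaled per CV by its
    importance).
    """

    n_points: int = 20
    swarm_min: int = 16
    swarm_max: int = 32
    swarm_len: int = 20
    restrained_len: int = 30
    max_iterations: int = 305
    averaging_window: int = 60
    base_force_constant: float = 3366.0
    drift_tolerance: float = np.inf
    convergence_tolerance: float = 1e-2
    fixed_endpoints: bool = True
    smoothing: float = 0.0

    def __post_init__(self):
        if not (0 < self.swarm_min <= self.swarm_max):
            raise ValueError("need 0 < swarm_min <= swarm_max")
        if self.averaging_window > self.max_iterations:
            raise ValueError("averaging_window must not exceed max_iterations")
        if self.n_points < 3:
            raise ValueError("a string needs at least 3 points")
        if self.base_force_constant < 0:
            raise ValueError("base_force_constant must be >= 0")


@dataclass
class StringPath:
    """Ordered points in weighted CV space, with iteration history."""

    points: np.ndarray
    iteration: int = 0
    fixed_endpoints: bool = True
    history: list = field(default_factory=list)

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if len(self.points) < 3:
            raise ValueError("a string needs at least 3 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive string points must be distinct")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def full_history(self) -> list[np.ndarray]:
        return self.history + [self.points]


@dataclass
class SwarmRecord:
    """Start/end CV coordinates of one point's swarm; carrier of the drift."""

    point_index: int
    starts: np.ndarray
    ends: np.ndarray
    failed: bool = False

    def __post_init__(self):
        self.starts = np.atleast_2d(np.asarray(self.starts, dtype=float))
        self.ends = np.atleast_2d(np.asarray(self.ends, dtype=float))
        if len(self.starts) != len(self.ends):
            raise ValueError("starts and ends must have equal length")

    @property
    def size(self) -> int:
        return len(self.starts)

    @property
    def drift(self) -> np.ndarray:
        """Mean displacement of the swarm in CV space."""
        return np.mean(self.ends - self.starts, axis=0)

    @property
    def drift_stderr(self) -> float:
        """Standard error of the drift vector (root of summed componentwise
        variances of the mean) — the adaptivity criterion."""
        if self.size < 2:
            return np.inf
        disp = self.ends - self.starts
        return float(np.sqrt(np.sum(np.var(disp, axis=0, ddof=1)) / self.size))


def _resample_once(points: np.ndarray, n_points: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = float(seg.sum())
    if total == 0:
        raise ValueError("degenerate (zero-length) path")
    s = np.concatenate([[0.0], np.cumsum(seg)]) / total
    t = np.linspace(0.0, 1.0, n_points)
    out = np.column_stack([np.interp(t, s, points[:, j]) for j in range(points.shape[1])])
    out[0], out[-1] = points[0], points[-1]  # endpoints exact
    return out


def _resample_equal_arclength(
    points: np.ndarray, n_points: int, tol: float = 1e-9, max_passes: int = 100
) -> np.ndarray:
    """Resample to uniform spacing; iterated until consecutive segment lengths
    are equal within ``tol`` (a single pass leaves unequal chords wherever a
    kink falls between samples)."""
    out = _resample_once(points, n_points)
    for _ in range(max_passes):
        seg = np.linalg.norm(np.diff(out, axis=0), axis=1)
        if seg.min() > 0 and seg.max() / seg.min() - 1.0 <= tol:
            break
        out = _resample_once(out, n_points)
    return out


def initialize_path(anchors, n_points: int, fixed_endpoints: bool = True) -> StringPath:
    """Piecewise-linear interpolation through the anchors, resampled to
    ``n_points`` at equal (weighted) arc length."""
    anchors = np.atleast_2d(np.asarray(anchors, dtype=float))
    if anchors.ndim == 2 and anchors.shape[1] == 1 and anchors.shape[0] == 1:
        raise ValueError("need at least two anchors")
    if len(anchors) < 2:
        raise ValueError("need at least two anchors")
    if np.allclose(anchors[0], anchors[-1]):
        raise ValueError("coincident endpoints")
    points = _resample_equal_arclength(anchors, n_points)
    return StringPath(points=points, fixed_endpoints=fixed_endpoints)


def reparametrize(path: StringPath, smoothing: float = 0.0) -> StringPath:
    """Equal-arc-length resampling in the weighted metric; endpoints exact.

    ``smoothing`` in [0, 1) mixes each interior point with the mean of its
    neighbours before resampling.
    """
    pts = path.points.copy()
    if smoothing > 0:
        interior = 0.5 * (pts[:-2] + pts[2:])
        pts[1:-1] = (1 - smoothing) * pts[1:-1] + smoothing * interior
    new_pts = _resample_equal_arclength(pts, len(pts))
    return StringPath(
        points=new_pts,
        iteration=path.iteration,
        fixed_endpoints=path.fixed_endpoints,
        history=path.history,
    )


def run_swarm(
    potential: AnalyticPotential,
    cv_set: CVSet,
    point: np.ndarray,
    config: StringConfig,
    params: EngineParams,
    point_index: int = 0,
    iteration: int = 0,
    x_state: np.ndarray | None = None,
) -> SwarmRecord:
    """Restrained-equilibrate at ``point`` (weighted CV space), then launch an
    adaptively sized swarm of short unbiased trajectories.

    Trajectories are added in batches beyond ``swarm_min`` until the standard
    error of the drift falls below ``drift_tolerance`` or ``swarm_max`` is
    reached.  A propagation failure marks the record failed instead of raising.
    """
    point = np.asarray(point, dtype=float)
    k = config.base_force_constant * cv_set.importance
    rng = substream_rng(params.seed, iteration, point_index)
    try:
        if x_state is None:
            x_state = cv_set.from_weighted(point)
        if config.restrained_len > 0:
            force = restraint_force(cv_set, point, k)
            x_state = propagate(
                x_state, potential, params, config.restrained_len, rng, extra_force=force
            )
        launch = np.asarray(x_state, dtype=float)
        starts, ends = [], []
        m = 0
        while True:
            batch = config.swarm_min if m == 0 else min(4, config.swarm_max - m)
            X0 = np.tile(launch, (batch, 1))
            if config.swarm_len > 0:
                X1 = propagate(X0, potential, params, config.swarm_len, rng)
            else:
                X1 = X0
            starts.append(cv_set.to_weighted(X0))
            ends.append(cv_set.to_weighted(X1))
            m += batch
            rec = SwarmRecord(point_index, np.concatenate(starts), np.concatenate(ends))
            if m >= config.swarm_max or rec.drift_stderr < config.drift_tolerance:
                return rec
    except PropagationError:
        return SwarmRecord(point_index, point[None, :], point[None, :], failed=True)


def update_string(path: StringPath, records: list[SwarmRecord], smoothing: float = 0.0) -> StringPath:
    """Displace movable points by their swarm drift, then reparametrize.

    Records must cover every movable point (point_index aligned with the
    path); failed records leave their point in place for this iteration.
    Fixed endpoints never move.
    """
    by_index = {r.point_index: r for r in records}
    new_pts = path.points.copy()
    lo, hi = (1, path.n_points - 1) if path.fixed_endpoints else (0, path.n_points)
    for i in range(lo, hi):
        rec = by_index.get(i)
        if rec is not None and not rec.failed:
            new_pts[i] = new_pts[i] + rec.drift
    moved = StringPath(
        points=new_pts,
        iteration=path.iteration + 1,
        fixed_endpoints=path.fixed_endpoints,
        history=path.history + [path.points.copy()],
    )
    return reparametrize(moved, smoothing=smoothing)


def check_convergence(history: list[np.ndarray], window: int, tolerance: float = 1e-2):
    """Average the strings over the trailing ``window`` iterations and compare
    with the preceding window's average.

    Returns ``(verdict, averaged_string)`` where verdict is True/False or the
    string ``"undetermined"`` when history is shorter than two windows.  The
    verdict is True when the RMS point distance between the two window means
    is below ``tolerance``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    strings = [np.asarray(s, dtype=float) for s in history]
    if len(strings) == 0:
        raise ValueError("empty history")
    avail = min(window, len(strings))
    averaged = np.mean(strings[-avail:], axis=0)
    if len(strings) < 2 * window:
        return "undetermined", averaged
    prev = np.mean(strings[-2 * window : -window], axis=0)
    rms = float(np.sqrt(np.mean(np.sum((averaged - prev) ** 2, axis=1))))
    return rms < tolerance, averaged


def simulation_budget(
    steered_time_us: float,
    n_restrained: int,
    restrained_ps: float,
    n_swarm: int,
    swarm_ps: float,
) -> float:
    """Total simulation time in µs: steered stage plus restrained
    equilibrations plus swarm trajectories, rounded to two decimals with
    exact decimal arithmetic."""
    vals = [steered_time_us, n_restrained, restrained_ps, n_swarm, swarm_ps]
    if any(v < 0 for v in vals):
        raise ValueError("budget inputs must be non-negative")
    total = (
        Decimal(str(steered_time_us))
        + Decimal(int(n_restrained)) * Decimal(str(restrained_ps)) / Decimal(1_000_000)
        + Decimal(int(n_swarm)) * Decimal(str(swarm_ps)) / Decimal(1_000_000)
    )
    return float(total.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


class StringSampler:
    """Orchestrates full string runs with batched propagation.

    All points' restrained equilibrations run as one vectorized batch, as do
    all swarm trajectories, so a full iteration costs a few dozen array
    operations regardless of the number of points.  Per-point launch
    configurations persist across iterations.
    """

    def __init__(
        self,
        potential: AnalyticPotential,
        cv_set: CVSet,
        path: StringPath,
        config: StringConfig,
        params: EngineParams,
    ):
        self.potential = potential
        self.cv_set = cv_set
        self.path = path
        self.config = config
        self.params = params
        self.x_states = cv_set.from_weighted(path.points)
        self.records_history: list[list[SwarmRecord]] = []
        self.n_restrained_run = 0
        self.n_swarm_run = 0

    # internal: batched restrained equilibration at the current anchors
    def _equilibrate(self, iteration: int) -> np.ndarray:
        cfg, p = self.config, self.params
        anchors = self.path.points
        k = cfg.base_force_constant * self.cv_set.importance
        rng = substream_rng(p.seed, iteration, 0)
        force = restraint_force(self.cv_set, anchors, k)
        self.x_states = propagate(
            self.x_states, self.potential, p, cfg.restrained_len, rng, extra_force=force
        )
        self.n_restrained_run += len(anchors)
        return self.x_states

    def _swarm_batch(self, launch: np.ndarray, sizes: np.ndarray, rng) -> list[np.ndarray]:
        """Propagate ``sizes[i]`` walkers from launch state i; returns per-point
        end batches."""
        X0 = np.repeat(launch, sizes, axis=0)
        X1 = propagate(X0, self.potential, self.params, self.config.swarm_len, rng)
        self.n_swarm_run += int(sizes.sum())
        split = np.cumsum(sizes)[:-1]
        return np.split(X1, split)

    def iterate(self) -> list[SwarmRecord]:
        """One full string iteration; returns the swarm records and updates the
        path in place."""
        cfg = self.config
        it = self.path.iteration
        launch = self._equilibrate(it)
        rng = substream_rng(self.params.seed, it, 1)
        n = len(launch)
        sizes = np.full(n, cfg.swarm_min)
        ends = self._swarm_batch(launch, sizes, rng)
        starts = [np.tile(launch[i], (sizes[i], 1)) for i in range(n)]
        w = self.cv_set.to_weighted
        records = [SwarmRecord(i, w(starts[i]), w(ends[i])) for i in range(n)]
        # adaptive growth toward swarm_max until the drift stderr converges
        while True:
            needy = [
                i
                for i, r in enumerate(records)
                if r.size < cfg.swarm_max and r.drift_stderr >= cfg.drift_tolerance
            ]
            if not needy:
                break
            add = np.array([min(4, cfg.swarm_max - records[i].size) for i in needy])
            extra_ends = self._swarm_batch(launch[needy], add, rng)
            for j, i in enumerate(needy):
                s = np.tile(w(launch[i]), (add[j], 1))
                records[i] = SwarmRecord(
                    i,
                    np.concatenate([records[i].starts, s]),
                    np.concatenate([records[i].ends, w(extra_ends[j])]),
                )
        self.records_history.append(records)
        self.path = update_string(self.path, records, smoothing=cfg.smoothing)
        return records

    def run(self, n_iterations: int | None = None, stop_on_convergence: bool = False):
        """Run up to ``n_iterations`` (default config.max_iterations).

        Returns ``(converged, averaged_string)`` from the final convergence
        check.
        """
        n_iterations = n_iterations or self.config.max_iterations
        verdict, averaged = "undetermined", self.path.points
        for _ in range(n_iterations):
            self.iterate()
            verdict, averaged = check_convergence(
                self.path.full_history(),
                self.config.averaging_window,
                self.config.convergence_tolerance,
            )
            if stop_on_convergence and verdict is True:
                break
        return verdict, averaged

    def production_swarms(self, n_rounds: int, seed_offset: int = 1_000_000):
        """Extra swarm rounds from the current (converged) string for
        free-energy estimation; returns (starts, ends) stacked over all rounds
        in *physical* CV coordinates."""
        cfg = self.config
        all_starts, all_ends = [], []
        for r in range(n_rounds):
            it = seed_offset + r
            launch = self._equilibrate(it)
            rng = substream_rng(self.params.seed, it, 1)
            sizes = np.full(len(launch), cfg.swarm_max)
            ends = self._swarm_batch(launch, sizes, rng)
            all_starts.append(np.repeat(launch, sizes, axis=0))
            all_ends.append(np.concatenate(ends))
        return np.concatenate(all_starts), np.concatenate(all_ends)
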