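"""Free-energy estimation from swarm transitions, and efficacy regression.

Swarm trajectories provide (start → end) transition pairs at a fixed lag.
Binning them on a grid gives a transition-count matrix; the regularized,
row-normalized matrix T (restricted to its largest strongly connected bin
set) has a stationary distribution π, and Boltzmann inversion F = −kT ln π
yields the free-energy surface.  Uncertainty comes from sampling transition
matrices from the row-wise Dirichlet posterior of the counts.  Microswitch
expectation values ⟨s⟩ = Σ s_b π_b and basin free-energy differences
ΔG = −kT ln(Σ_A π / Σ_B π) feed a linear regression against experimental
efficacy (Emax), which can then predict the efficacy of held-out ligands.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .engine import substream_rng

__all__ = [
    "GridSpec",
    "TransitionModel",
    "FESurface",
    "BasinDef",
    "EfficacyModel",
    "count_transitions",
    "estimate_transition_matrix",
    "reversible_stationary",
    "boltzmann_invert",
    "posterior_surfaces",
    "expectation_value",
    "delta_g",
    "fit_efficacy",
    "predict_efficacy",
    "implied_timescales",
]


@dataclass
class GridSpec:
    """Regular grid along chosen variables; ``edges[v]`` strictly increasing."""

    edges: list
    variables: list[str] | None = None
    max_bins: int = 100_000

    def __post_init__(self):
        self.edges = [np.asarray(e, dtype=float) for e in self.edges]
        for v, e in enumerate(self.edges):
            if e.ndim != 1 or len(e) < 2 or np.any(np.diff(e) <= 0):
                raise ValueError(f"edges for variable {v} must be strictly increasing")
        if self.n_bins > self.max_bins:
            raise ValueError(f"grid has {self.n_bins} bins, cap is {self.max_bins}")

    @classmethod
    def regular(cls, mins, maxs, n_bins, variables=None) -> "GridSpec":
        mins, maxs = np.atleast_1d(mins), np.atleast_1d(maxs)
        n_bins = np.broadcast_to(np.atleast_1d(n_bins), mins.shape)
        edges = [np.linspace(lo, hi, nb + 1) for lo, hi, nb in zip(mins, maxs, n_bins)]
        return cls(edges=edges, variables=variables)

    @property
    def ndim(self) -> int:
        return len(self.edges)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(e) - 1 for e in self.edges)

    @property
    def n_bins(self) -> int:
        return int(np.prod(self.shape))

    @property
    def centers(self) -> np.ndarray:
        """Bin centers as an (n_bins, ndim) array in C (row-major) bin order."""
        per_dim = [0.5 * (e[:-1] + e[1:]) for e in self.edges]
        mesh = np.meshgrid(*per_dim, indexing="ij")
        return np.column_stack([m.ravel() for m in mesh])

    def assign(self, points) -> np.ndarray:
        """Flat bin index per point; −1 for points outside the grid."""
        x = np.atleast_2d(np.asarray(points, dtype=float))
        if x.shape[1] != self.ndim:
            raise ValueError(f"points have {x.shape[1]} dims, grid has {self.ndim}")
        idx = np.zeros(len(x), dtype=int)
        valid = np.ones(len(x), dtype=bool)
        for v, e in enumerate(self.edges):
            iv = np.searchsorted(e, x[:, v], side="right") - 1
            # points exactly at the upper edge belong to the last bin
            iv[x[:, v] == e[-1]] = len(e) - 2
            ok = (iv >= 0) & (iv < len(e) - 1)
            valid &= ok
            iv = np.clip(iv, 0, len(e) - 2)
            idx = idx * (len(e) - 1) + iv
        idx[~valid] = -1
        return idx


def count_transitions(starts, ends, grid: GridSpec) -> tuple[np.ndarray, int]:
    """Bin (start → end) pairs; returns the count matrix and the number of
    pairs dropped because either endpoint fell outside the grid."""
    i = grid.assign(starts)
    j = grid.assign(ends)
    keep = (i >= 0) & (j >= 0)
    dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("all transitions fall outside the grid")
    n = grid.n_bins
    counts = np.zeros((n, n))
    np.add.at(counts, (i[keep], j[keep]), 1.0)
    return counts, dropped


@dataclass
class TransitionModel:
    """Regularized row-stochastic transition matrix restricted to the largest
    strongly connected bin set, with stationary distribution π."""

    counts: np.ndarray
    pseudo_count: float
    transition_matrix: np.ndarray
    stationary: np.ndarray
    active_bins: np.ndarray  # indices into the full grid

    @property
    def n_states(self) -> int:
        return len(self.active_bins)


def _largest_scc(counts: np.ndarray) -> np.ndarray:
    graph = csr_matrix((counts > 0).astype(int))
    n_comp, labels = connected_components(graph, directed=True, connection="strong")
    # among components, keep the one with most observed transitions
    best, best_weight = 0, -1.0
    for c in range(n_comp):
        members = labels == c
        weight = counts[np.ix_(members, members)].sum()
        if weight > best_weight:
            best, best_weight = c, weight
    return np.flatnonzero(labels == best)


def _stationary_from_T(T: np.ndarray) -> np.ndarray:
    vals, vecs = sla.eig(T, left=True, right=False)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def reversible_stationary(
    counts, n_iter: int = 5000, tol: float = 1e-13, return_flux: bool = False
):
    """Maximum-likelihood stationary distribution under a detailed-balance
    constraint, by the standard self-consistent iteration on the symmetrized
    counts.

    For reversible dynamics sampled bin-conditionally this estimator removes
    the error that accumulates in the row-wise estimate along chains of bins
    (each forward/backward count ratio is noisy; detailed balance couples
    them).  ``counts`` must already be restricted to a connected bin set.
    With ``return_flux`` also returns the symmetric equilibrium flux matrix X
    (x_ij = π_i T_ij).
    """
    C = np.asarray(counts, dtype=float)
    Csym = C + C.T
    ci = C.sum(axis=1)
    pi = Csym.sum(axis=1)
    pi = pi / pi.sum()
    X = np.diag(pi)
    for _ in range(n_iter):
        denom = ci[:, None] / pi[:, None] + ci[None, :] / pi[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            X = np.where(Csym > 0, Csym / denom, 0.0)
        new = X.sum(axis=1)
        norm = new.sum()
        new = new / norm
        if np.max(np.abs(new - pi)) < tol:
            pi = new
            X = X / norm
            break
        pi = new
        X = X / norm
    if return_flux:
        return pi, X
    return pi


def estimate_transition_matrix(
    counts, pseudo_count: float | None = None, reversible: bool = False
) -> TransitionModel:
    """Row-normalize (counts + pseudo_count) over the largest strongly
    connected bin set and compute its stationary distribution.

    ``pseudo_count`` defaults to 1/n_bins per element — a weak regularization
    that keeps the matrix ergodic on the connected set without drowning real
    counts.  Dropped (disconnected) bins are reported via a warning.  With
    ``reversible=True`` the stationary distribution is the detailed-balance
    constrained maximum-likelihood estimate (:func:`reversible_stationary`)
    and the transition matrix is its reversible MLE.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("counts must be a square matrix")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if counts.sum() == 0:
        raise ValueError("no transitions observed; cannot estimate")
    if pseudo_count is None:
        pseudo_count = 1.0 / counts.shape[0]
    active = _largest_scc(counts)
    if len(active) < counts.shape[0]:
        dropped = sorted(set(range(counts.shape[0])) - set(active.tolist()))
        warnings.warn(
            f"grid not fully connected; dropped {len(dropped)} bins: {dropped[:20]}"
            + ("..." if len(dropped) > 20 else ""),
            stacklevel=2,
        )
    sub = counts[np.ix_(active, active)] + pseudo_count
    T = sub / sub.sum(axis=1, keepdims=True)
    if reversible:
        pi, flux = reversible_stationary(counts[np.ix_(active, active)], return_flux=True)
        # reversible MLE transition matrix: T_ij = x_ij / π_i (flux symmetric)
        T = flux / pi[:, None]
        T = T / T.sum(axis=1, keepdims=True)
    else:
        pi = _stationary_from_T(T)
    return TransitionModel(
        counts=counts,
        pseudo_count=float(pseudo_count),
        transition_matrix=T,
        stationary=pi,
        active_bins=active,
    )


@dataclass
class FESurface:
    """Binned free energies in kT, minimum shifted to zero.

    ``F`` and ``stderr`` are aligned with ``bin_centers``; bins never visited
    carry F = +inf ("unbounded") and are excluded from the min shift.
    """

    bin_centers: np.ndarray
    F: np.ndarray
    stderr: np.ndarray | None = None
    n_posterior_samples: int = 0
    kT: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        centers = np.atleast_2d(self.bin_centers)
        cols = {f"center_{j}": centers[:, j] for j in range(centers.shape[1])}
        cols["F"] = self.F
        if self.stderr is not None:
            cols["stderr"] = self.stderr
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def _invert(pi: np.ndarray, kT: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        F = -kT * np.log(pi)
    finite = np.isfinite(F)
    if finite.any():
        F = F - F[finite].min()
    return F


def boltzmann_invert(pi, kT: float = 1.0, bin_centers=None) -> FESurface:
    """F = −kT ln π, shifted so the minimum over visited bins is zero;
    zero-probability bins are marked unbounded (F = +inf)."""
    pi = np.asarray(pi, dtype=float)
    F = _invert(pi, kT)
    if bin_centers is None:
        bin_centers = np.arange(len(pi), dtype=float)[:, None]
    return FESurface(bin_centers=np.asarray(bin_centers), F=F, kT=kT)


def posterior_surfaces(
    counts,
    n_samples: int = 1000,
    seed: int = 0,
    pseudo_count: float | None = None,
    kT: float = 1.0,
    bin_centers=None,
) -> FESurface:
    """Sample transition matrices from the row-wise Dirichlet posterior of the
    counts, invert each stationary distribution, and report the pointwise mean
    free energy with its sample standard error.

    With ``n_samples = 1`` the stderr is undefined (NaN) and flagged by a
    warning.
    """
    counts = np.asarray(counts, dtype=float)
    model = estimate_transition_matrix(counts, pseudo_count)
    active = model.active_bins
    alpha = counts[np.ix_(active, active)] + model.pseudo_count
    rng = substream_rng(seed, 11)
    Fs = np.empty((n_samples, len(active)))
    for s in range(n_samples):
        T = np.vstack([rng.dirichlet(row) for row in alpha])
        pi = _stationary_from_T(T)
        Fs[s] = -kT * np.log(pi)
    # π is normalized, so F = −kT ln π needs no per-sample alignment; only the
    # reported mean is min-shifted
    mean_F = Fs.mean(axis=0)
    mean_F = mean_F - mean_F.min()
    if n_samples < 2:
        warnings.warn("stderr undefined for n_samples < 2", stacklevel=2)
        stderr = np.full(len(active), np.nan)
    else:
        stderr = Fs.std(axis=0, ddof=1)
    if bin_centers is None:
        bin_centers = np.arange(counts.shape[0], dtype=float)[:, None]
    centers = np.asarray(bin_centers)[active]
    return FESurface(
        bin_centers=centers,
        F=mean_F,
        stderr=stderr,
        n_posterior_samples=n_samples,
        kT=kT,
    )


def expectation_value(observable, pi) -> float:
    """⟨s⟩ = Σ_bin s_bin π_bin over the retained bins."""
    s = np.asarray(observable, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if s.shape != pi.shape:
        raise ValueError(f"observable length {s.shape} != stationary length {pi.shape}")
    return float(np.sum(s * pi))


@dataclass(frozen=True)
class BasinDef:
    """A named basin: a predicate over bin-center coordinates."""

    name: str
    predicate: Callable[[np.ndarray], np.ndarray]

    def mask(self, bin_centers: np.ndarray) -> np.ndarray:
        centers = np.atleast_2d(np.asarray(bin_centers, dtype=float))
        m = np.asarray(self.predicate(centers), dtype=bool)
        if m.shape != (len(centers),):
            raise ValueError(f"basin {self.name!r}: predicate must return one bool per bin")
        return m

    @classmethod
    def box(cls, name: str, lo, hi) -> "BasinDef":
        lo = np.atleast_1d(np.asarray(lo, dtype=float))
        hi = np.atleast_1d(np.asarray(hi, dtype=float))
        return cls(name, lambda c: np.all((c >= lo) & (c <= hi), axis=1))


def delta_g(pi, basin_a, basin_b, kT: float = 1.0, bin_centers=None) -> float:
    """ΔG(A, B) = −kT ln(Σ_A π / Σ_B π); negative when A is more stable.

    Basins may be boolean masks over bins or :class:`BasinDef` objects
    evaluated on ``bin_centers``.  A basin of zero probability yields signed
    infinity with a warning.
    """
    pi = np.asarray(pi, dtype=float)
    masks = []
    for basin in (basin_a, basin_b):
        if isinstance(basin, BasinDef):
            if bin_centers is None:
                raise ValueError("BasinDef basins require bin_centers")
            masks.append(basin.mask(bin_centers))
        else:
            masks.append(np.asarray(basin, dtype=bool))
    ma, mb = masks
    if np.any(ma & mb):
        raise ValueError("basins must be disjoint")
    if not ma.any() or not mb.any():
        raise ValueError("each basin must contain at least one bin")
    pa, pb = float(pi[ma].sum()), float(pi[mb].sum())
    if pa == 0 or pb == 0:
        warnings.warn("a basin has zero probability; ΔG is infinite", stacklevel=2)
        return float(np.inf if pa == 0 else -np.inf)
    return float(-kT * np.log(pa / pb))


@dataclass
class EfficacyModel:
    """OLS line relating a microswitch statistic to efficacy (Emax)."""

    slope: float
    intercept: float
    pearson_r: float
    stderr: float
    residual_std: float
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json(self, path) -> None:
        payload = {
            "slope": self.slope,
            "intercept": self.intercept,
            "pearson_r": self.pearson_r,
            "stderr": self.stderr,
            "residual_std": self.residual_std,
            "table": self.table.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EfficacyModel":
        with open(path) as fh:
            payload = json.load(fh)
        table = pd.DataFrame(payload.pop("table"))
        return cls(table=table, **payload)


def fit_efficacy(expectations, emax, ligands: Sequence[str] | None = None) -> EfficacyModel:
    """Ordinary least squares Emax ≈ slope·⟨s⟩ + intercept with Pearson r.

    Requires ≥ 3 ligands; zero variance in the expectations is an error, and
    constant Emax gives slope 0 with r flagged as NaN.
    """
    x = np.asarray(expectations, dtype=float)
    y = np.asarray(emax, dtype=float)
    if len(x) != len(y):
        raise ValueError("expectations and emax must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 ligands to fit")
    if np.var(x) == 0:
        raise ValueError("zero variance in expectation values")
    if np.var(y) == 0:
        warnings.warn("constant Emax: correlation undefined", stacklevel=2)
        res_slope, res_intercept, res_r, res_se = 0.0, float(y[0]), np.nan, 0.0
    else:
        res = stats.linregress(x, y)
        res_slope, res_intercept, res_r, res_se = (
            float(res.slope),
            float(res.intercept),
            float(res.rvalue),
            float(res.stderr),
        )
    resid = y - (res_slope * x + res_intercept)
    dof = len(x) - 2
    residual_std = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else np.nan
    if ligands is None:
        ligands = [f"ligand{i}" for i in range(len(x))]
    table = pd.DataFrame({"ligand": list(ligands), "expectation": x, "emax": y})
    return EfficacyModel(
        slope=res_slope,
        intercept=res_intercept,
        pearson_r=res_r,
        stderr=res_se,
        residual_std=residual_std,
        table=table,
    )


def predict_efficacy(model: EfficacyModel, expectation, confidence: float = 0.95):
    """Predicted Emax = slope·x + intercept with a prediction interval from the
    residual variance of the fit."""
    if model is None or not np.isfinite(model.slope):
        raise ValueError("model is not fitted")
    x = np.asarray(expectation, dtype=float)
    yhat = model.slope * x + model.intercept
    n = len(model.table)
    xt = model.table["expectation"].to_numpy()
    sxx = float(np.sum((xt - xt.mean()) ** 2))
    if n > 2 and np.isfinite(model.residual_std) and sxx > 0:
        se = model.residual_std * np.sqrt(1.0 + 1.0 / n + (x - xt.mean()) ** 2 / sxx)
        tval = stats.t.ppf(0.5 + confidence / 2.0, n - 2)
        half = tval * se
    else:
        half = np.full_like(np.atleast_1d(yhat), np.nan)
    return yhat, (yhat - half, yhat + half)


def implied_timescales(counts, lags: Sequence[int], base_lag: int = 1, pseudo_count=None):
    """Diagnostic: slowest implied timescale t₂ = −lag/ln λ₂ at multiples of
    the base lag, estimated by matrix powers of the single-lag model.  A flat
    curve supports the Markov assumption at the swarm length used."""
    model = estimate_transition_matrix(counts, pseudo_count)
    out = []
    for lag in lags:
        T = np.linalg.matrix_power(model.transition_matrix, int(lag))
        vals = np.sort(np.abs(np.linalg.eigvals(T)))[::-1]
        lam2 = vals[1] if len(vals) > 1 else np.nan
        t2 = -lag * base_lag / np.log(lam2) if 0 < lam2 < 1 else np.inf
        out.append((lag * base_lag, float(t2)))
    return out
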