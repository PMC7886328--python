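"""Analytic model potentials standing in for molecular free-energy landscapes.

Every potential exposes an energy (in kT units), its analytic gradient, and —
where known — the locations of its minima and saddle points, so that sampling
and path-finding algorithms can be validated against closed-form truth.
Energies are defined globally (no domain clipping); confining forms are used
in tests.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "AnalyticPotential",
    "Flat",
    "Harmonic",
    "DoubleWell1D",
    "MullerBrown",
    "GaussianMixturePotential",
    "get_potential",
    "register_potential",
    "POTENTIAL_REGISTRY",
]


class AnalyticPotential:
    """Energy/gradient contract used by the Brownian engine.

    Subclasses implement :meth:`energy` and :meth:`gradient` accepting either a
    single point of shape ``(ndim,)`` or a batch ``(n, ndim)``.  ``known_minima``
    and ``known_saddles`` list stationary points (possibly empty) used as
    oracles by path methods.
    """

    ndim: int = 1
    known_minima: list = []
    known_saddles: list = []

    def energy(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def numerical_gradient(self, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
        """Central-difference gradient, the reference for the analytic one."""
        x = np.asarray(x, dtype=float)
        g = np.empty_like(x)
        for j in range(x.shape[-1]):
            xp, xm = x.copy(), x.copy()
            xp[..., j] += h
            xm[..., j] -= h
            g[..., j] = (self.energy(xp) - self.energy(xm)) / (2.0 * h)
        return g

    def hessian(self, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
        """Numerical Hessian (used to classify stationary points)."""
        x = np.asarray(x, dtype=float)
        d = x.shape[-1]
        H = np.empty((d, d))
        for j in range(d):
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            H[:, j] = (self.gradient(xp) - self.gradient(xm)) / (2.0 * h)
        return 0.5 * (H + H.T)


def _batchify(x):
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    return (x[None, :] if squeeze else x), squeeze


class Flat(AnalyticPotential):
    """Zero potential; pure diffusion."""

    def __init__(self, ndim: int = 1):
        self.ndim = ndim
        self.known_minima = []
        self.known_saddles = []

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return np.zeros(x.shape[:-1])

    def gradient(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))


class Harmonic(AnalyticPotential):
    """U(x) = ½ Σ κ_j (x_j − c_j)²."""

    def __init__(self, kappa=1.0, center=None, ndim: int | None = None):
        kappa = np.atleast_1d(np.asarray(kappa, dtype=float))
        if ndim is None:
            ndim = len(kappa)
        if len(kappa) == 1 and ndim > 1:
            kappa = np.full(ndim, kappa[0])
        self.kappa = kappa
        self.center = np.zeros(ndim) if center is None else np.asarray(center, float)
        self.ndim = ndim
        self.known_minima = [self.center.copy()]
        self.known_saddles = []

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return 0.5 * np.sum(self.kappa * (x - self.center) ** 2, axis=-1)

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        return self.kappa * (x - self.center)


class DoubleWell1D(AnalyticPotential):
    """Tilted quartic double well U(x) = h (x² − 1)² + a·x.

    ``h`` sets the barrier height (in kT) of the untilted well; ``a`` tilts the
    landscape so the left well (x ≈ −1) is deeper for a > 0.  Minima and the
    saddle (barrier top) are located numerically at construction.
    """

    ndim = 1

    def __init__(self, barrier: float = 3.0, tilt: float = 0.0):
        self.barrier = float(barrier)
        self.tilt = float(tilt)
        self.known_minima = [np.array([r]) for r in self._stationary(minima=True)]
        self.known_saddles = [np.array([r]) for r in self._stationary(minima=False)]

    def _stationary(self, minima: bool):
        # roots of U'(x) = 4h x (x²−1) + a
        roots = np.roots([4 * self.barrier, 0.0, -4 * self.barrier, self.tilt])
        roots = np.sort(roots[np.abs(roots.imag) < 1e-12].real)
        curv = 12 * self.barrier * roots**2 - 4 * self.barrier
        keep = curv > 0 if minima else curv < 0
        return roots[keep]

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        xi = x[..., 0]
        return self.barrier * (xi**2 - 1.0) ** 2 + self.tilt * xi

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        xi = x[..., 0]
        g = 4.0 * self.barrier * xi * (xi**2 - 1.0) + self.tilt
        return g[..., None]


# Standard Müller–Brown parameters.
_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])


class MullerBrown(AnalyticPotential):
    """The four-term Müller–Brown surface, the standard 2D benchmark for
    minimum-energy-path methods.

    ``scale`` multiplies the energy (the raw surface has barriers of order
    100); ``scale≈0.05`` brings the barriers to a few kT so that a unit-kT
    Brownian walker samples meaningfully.  Stationary points are independent
    of scale.
    """

    ndim = 2

    def __init__(self, scale: float = 1.0):
        self.scale = float(scale)
        self.known_minima = [
            np.array([-0.5582236346, 1.4417258418]),
            np.array([0.6234994049, 0.0280377585]),
            np.array([-0.0500108229, 0.4666941049]),
        ]
        self.known_saddles = [
            np.array([-0.8220015587, 0.6243128028]),
            np.array([0.2124865821, 0.2929883251]),
        ]

    def _terms(self, x):
        x = np.asarray(x, dtype=float)
        dx = x[..., 0, None] - _MB_x0
        dy = x[..., 1, None] - _MB_y0
        expo = _MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2
        return dx, dy, _MB_A * np.exp(expo)

    def energy(self, x):
        _, _, t = self._terms(x)
        return self.scale * np.sum(t, axis=-1)

    def gradient(self, x):
        dx, dy, t = self._terms(x)
        gx = np.sum(t * (2 * _MB_a * dx + _MB_b * dy), axis=-1)
        gy = np.sum(t * (_MB_b * dx + 2 * _MB_c * dy), axis=-1)
        return self.scale * np.stack([gx, gy], axis=-1)


class GaussianMixturePotential(AnalyticPotential):
    """U(x) = −kT ln Σ_i w_i N(x; μ_i, Σ_i): a landscape with basins at the
    component means."""

    def __init__(self, means: Sequence, covariances: Sequence, weights: Sequence | None = None, kT: float = 1.0):
        self.means = [np.atleast_1d(np.asarray(m, float)) for m in means]
        self.ndim = len(self.means[0])
        self.covs = [np.atleast_2d(np.asarray(c, float)) for c in covariances]
        n = len(self.means)
        w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, float)
        self.weights = w / w.sum()
        self.kT = float(kT)
        self._precisions = [np.linalg.inv(c) for c in self.covs]
        self._norms = [
            wi / np.sqrt(((2 * np.pi) ** self.ndim) * np.linalg.det(c))
            for wi, c in zip(self.weights, self.covs)
        ]
        self.known_minima = [m.copy() for m in self.means]
        self.known_saddles = []

    def _density_and_grad(self, x):
        x, _ = _batchify(x)
        p = np.zeros(x.shape[0])
        gp = np.zeros_like(x)
        for mu, P, norm in zip(self.means, self._precisions, self._norms):
            d = x - mu
            q = np.einsum("ni,ij,nj->n", d, P, d)
            comp = norm * np.exp(-0.5 * q)
            p += comp
            gp += -comp[:, None] * (d @ P.T)
        return p, gp

    def energy(self, x):
        xb, squeeze = _batchify(x)
        p, _ = self._density_and_grad(xb)
        e = -self.kT * np.log(p)
        return e[0] if squeeze else e

    def gradient(self, x):
        xb, squeeze = _batchify(x)
        p, gp = self._density_and_grad(xb)
        g = -self.kT * gp / p[:, None]
        return g[0] if squeeze else g


PotentialFactory = Callable[..., AnalyticPotential]

POTENTIAL_REGISTRY: dict[str, PotentialFactory] = {
    "flat": Flat,
    "harmonic": Harmonic,
    "double_well_1d": DoubleWell1D,
    "muller_brown": MullerBrown,
    "gaussian_mixture": GaussianMixturePotential,
}


def register_potential(name: str, factory: PotentialFactory) -> None:
    """Plug-in contract: register a custom potential factory under ``name``."""
    POTENTIAL_REGISTRY[name] = factory


def get_potential(name: str, **params) -> AnalyticPotential:
    try:
        factory = POTENTIAL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown potential {name!r}; available: {sorted(POTENTIAL_REGISTRY)}"
        ) from None
    return factory(**params)
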