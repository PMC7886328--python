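"""Collective variables: feature definitions, filtering, unit scaling and
importance weighting.

The path-sampling algorithms all operate in *weighted scaled CV space*: every
CV is first min–max scaled to be unitless (roughly in [0, 1] over the sampled
range), then multiplied by its importance weight in (0, 1], so that Euclidean
distances, restraint forces and swarm drifts emphasise the degrees of freedom
that matter for the transition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FeatureSpec",
    "CVSet",
    "FeatureError",
    "inverse_distance_features",
    "range_filter_features",
    "scale_unit",
    "unscale_unit",
    "weigh_point",
    "identity_cvset",
]


class FeatureError(ValueError):
    """Raised for ill-defined feature evaluations (e.g. non-positive distance)."""


@dataclass(frozen=True)
class FeatureSpec:
    """One candidate feature: an inverse inter-site distance or a raw coordinate."""

    id: int
    member_a: str
    member_b: str = ""
    transform: str = "inverse_distance"

    def __post_init__(self):
        if self.transform not in ("inverse_distance", "raw_coordinate"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "inverse_distance" and self.member_a == self.member_b:
            raise ValueError(
                f"feature {self.id}: distance members must be distinct ({self.member_a!r})"
            )

    @property
    def label(self) -> str:
        if self.transform == "raw_coordinate":
            return self.member_a
        return f"{self.member_a}-{self.member_b}"


def inverse_distance_features(distances, specs: Sequence[FeatureSpec]) -> np.ndarray:
    """Map raw distances (Å) to features: 1/d for distance pairs, identity for
    raw coordinates.

    ``distances`` is an array aligned with ``specs`` along its last axis
    (a single frame ``(F,)`` or a batch ``(n, F)``).
    """
    d = np.asarray(distances, dtype=float)
    if d.shape[-1] != len(specs):
        raise ValueError(f"got {d.shape[-1]} values for {len(specs)} feature specs")
    out = d.copy()
    for j, spec in enumerate(specs):
        if spec.transform == "inverse_distance":
            col = d[..., j]
            if np.any(col <= 0):
                raise FeatureError(
                    f"non-positive distance for pair {spec.label} (feature {spec.id})"
                )
            out[..., j] = 1.0 / col
    return out


def range_filter_features(
    distance_matrix,
    window: tuple[float, float] = (6.0, 8.0),
    mode: str = "any",
    quantile: float = 0.5,
) -> np.ndarray:
    """Indices of features whose sampled distances visit the window [low, high] Å.

    ``mode='any'`` (default) retains a feature if any frame lies in-window;
    ``mode='quantile'`` is the stricter reading requiring the given quantile of
    frames to lie in-window.
    """
    X = np.asarray(distance_matrix, dtype=float)
    if X.size == 0:
        raise FeatureError("empty distance matrix")
    if X.ndim != 2:
        raise ValueError("distance matrix must be frames x features")
    low, high = window
    if not low < high:
        raise ValueError(f"window must satisfy low < high, got {window}")
    inside = (X >= low) & (X <= high)
    if mode == "any":
        keep = inside.any(axis=0)
    elif mode == "quantile":
        keep = inside.mean(axis=0) >= quantile
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return np.flatnonzero(keep)


def scale_unit(values, bounds) -> np.ndarray:
    """(v − min) / (max − min) per CV.  Out-of-range inputs map outside [0, 1]
    (linear extrapolation) and are permitted."""
    v = np.asarray(values, dtype=float)
    b = np.asarray(bounds, dtype=float)
    lo, hi = b[..., 0], b[..., 1]
    if not np.all(np.isfinite(b)):
        raise ValueError("bounds must be finite")
    if np.any(hi <= lo):
        bad = np.flatnonzero(hi <= lo)
        raise ValueError(f"degenerate bounds (max <= min) for CVs {bad.tolist()}")
    return (v - lo) / (hi - lo)


def unscale_unit(scaled, bounds) -> np.ndarray:
    """Inverse of :func:`scale_unit`."""
    s = np.asarray(scaled, dtype=float)
    b = np.asarray(bounds, dtype=float)
    lo, hi = b[..., 0], b[..., 1]
    return lo + s * (hi - lo)


def weigh_point(scaled, importance) -> np.ndarray:
    """Elementwise product of a scaled point with per-CV importance weights."""
    s = np.asarray(scaled, dtype=float)
    w = np.asarray(importance, dtype=float)
    if s.shape[-1] != w.shape[-1] if w.ndim else len(w):
        raise ValueError(f"length mismatch: point {s.shape[-1]}, importance {len(w)}")
    return s * w


@dataclass
class CVSet:
    """A set of CVs with min–max bounds and importance weights.

    ``bounds`` has shape (n_cv, 2); ``importance`` entries lie in (0, 1].
    ``to_weighted`` maps physical CV values into the weighted scaled space in
    which all string/state-sampler distances are Euclidean.
    """

    bounds: np.ndarray
    importance: np.ndarray
    specs: list[FeatureSpec] = field(default_factory=list)

    def __post_init__(self):
        self.bounds = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        self.importance = np.atleast_1d(np.asarray(self.importance, dtype=float))
        if self.bounds.shape != (len(self.importance), 2):
            raise ValueError("bounds must be (n_cv, 2) matching importance length")
        if np.any(self.bounds[:, 1] <= self.bounds[:, 0]):
            raise ValueError("each CV needs bounds.min < bounds.max")
        if np.any((self.importance <= 0) | (self.importance > 1)):
            raise ValueError("importance weights must lie in (0, 1]")

    @property
    def n_cv(self) -> int:
        return len(self.importance)

    @property
    def ranges(self) -> np.ndarray:
        return self.bounds[:, 1] - self.bounds[:, 0]

    def scale(self, values):
        return scale_unit(values, self.bounds)

    def unscale(self, scaled):
        return unscale_unit(scaled, self.bounds)

    def weigh(self, scaled):
        return weigh_point(scaled, self.importance)

    def to_weighted(self, values):
        return self.weigh(self.scale(values))

    def from_weighted(self, weighted):
        return self.unscale(np.asarray(weighted, dtype=float) / self.importance)

    @property
    def jacobian_diag(self) -> np.ndarray:
        """d(weighted scaled CV)/d(physical CV): importance / range per CV."""
        return self.importance / self.ranges

    # -- serialization ------------------------------------------------------
    def to_files(self, table_path, sidecar_path=None, window=None) -> None:
        """Write the CV table (pair label, importance) and a JSON sidecar with
        bounds (and the distance filter window, if any)."""
        table_path = Path(table_path)
        lines = []
        for j in range(self.n_cv):
            label = self.specs[j].label if self.specs else f"cv{j}"
            lines.append(f"{label}\t{self.importance[j]:.17g}")
        table_path.write_text("\n".join(lines) + "\n")
        if sidecar_path is None:
            sidecar_path = table_path.with_suffix(".json")
        meta = {"bounds": self.bounds.tolist()}
        if window is not None:
            meta["distance_window"] = list(window)
        Path(sidecar_path).write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_files(cls, table_path, sidecar_path=None) -> "CVSet":
        table_path = Path(table_path)
        labels, importance = [], []
        for line in table_path.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            label, imp = line.rsplit("\t", 1) if "\t" in line else line.rsplit(None, 1)
            labels.append(label.strip())
            importance.append(float(imp))
        if sidecar_path is None:
            sidecar_path = table_path.with_suffix(".json")
        sidecar_path = Path(sidecar_path)
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
            bounds = np.asarray(meta["bounds"], dtype=float)
        else:
            bounds = np.tile([0.0, 1.0], (len(labels), 1))
        specs = []
        for j, label in enumerate(labels):
            if "-" in label:
                a, b = label.split("-", 1)
                specs.append(FeatureSpec(j, a, b))
            else:
                specs.append(FeatureSpec(j, label, transform="raw_coordinate"))
        return cls(bounds=bounds, importance=np.asarray(importance), specs=specs)


def identity_cvset(bounds, importance=None, names: Sequence[str] | None = None) -> CVSet:
    """A CVSet whose physical CVs are the engine coordinates themselves —
    the natural choice for analytic toy potentials."""
    bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
    n = len(bounds)
    if importance is None:
        importance = np.ones(n)
    if names is None:
        names = [f"x{j}" for j in range(n)]
    specs = [FeatureSpec(j, names[j], transform="raw_coordinate") for j in range(n)]
    return CVSet(bounds=bounds, importance=np.asarray(importance), specs=specs)
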