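"""Labeled conformational ensembles.

A :class:`LabeledEnsemble` holds a frames × features matrix with one class
label per frame — the synthetic analogue of per-ligand active-like state
ensembles, where each "ligand" induces its own distribution over inter-residue
features.  The generator draws each class from a Gaussian mixture, so
downstream importance methods can be validated on planted, closed-form
class differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import substream_rng

__all__ = ["LabeledEnsemble", "MixtureComponent", "generate_labeled_ensembles"]


@dataclass
class LabeledEnsemble:
    """frames × features matrix with a class label per frame."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] | None = None

    def __post_init__(self):
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.features.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.features.shape[0]} frames but {len(self.labels)} labels"
            )
        if self.feature_names is not None and len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length must match feature count")

    @property
    def n_frames(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def require_supervised(self) -> None:
        if self.n_frames == 0:
            raise ValueError("empty ensemble")
        if len(self.classes) < 2:
            raise ValueError("supervised operations need at least 2 classes")

    def class_view(self, label) -> np.ndarray:
        return self.features[self.labels == label]

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Delimited text, one frame per row, last column = label.  Floats are
        written with full precision so the round-trip is exact."""
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df["label"] = self.labels
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "LabeledEnsemble":
        df = pd.read_csv(path, float_precision="round_trip")
        labels = df.pop("label").to_numpy()
        names = list(df.columns)
        default = [f"f{j}" for j in range(len(names))]
        return cls(df.to_numpy(dtype=float), labels,
                   feature_names=None if names == default else names)

    def to_hdf5(self, path) -> None:
        """Columnar binary container (HDF5): datasets features, labels and
        optionally feature_names."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("features", data=self.features)
            f.create_dataset("labels", data=np.asarray(self.labels, dtype="S"))
            if self.feature_names is not None:
                f.create_dataset("feature_names", data=np.asarray(self.feature_names, dtype="S"))

    @classmethod
    def from_hdf5(cls, path) -> "LabeledEnsemble":
        import h5py

        with h5py.File(path, "r") as f:
            features = f["features"][...]
            labels = np.array([s.decode() for s in f["labels"][...]])
            names = None
            if "feature_names" in f:
                names = [s.decode() for s in f["feature_names"][...]]
        return cls(features, labels, feature_names=names)


@dataclass(frozen=True)
class MixtureComponent:
    """One Gaussian component (mean, covariance, weight) of a class mixture."""

    mean: tuple
    covariance: tuple
    weight: float = 1.0


def _as_components(spec) -> list[tuple[np.ndarray, np.ndarray, float]]:
    comps = []
    for comp in spec:
        if isinstance(comp, MixtureComponent):
            mean, cov, w = comp.mean, comp.covariance, comp.weight
        else:
            mean, cov, w = comp
        mean = np.atleast_1d(np.asarray(mean, dtype=float))
        cov = np.asarray(cov, dtype=float)
        if cov.ndim == 0:
            cov = np.eye(len(mean)) * float(cov)
        elif cov.ndim == 1:
            cov = np.diag(cov)
        comps.append((mean, cov, float(w)))
    return comps


def generate_labeled_ensembles(
    class_specs: Mapping[str, Sequence],
    n_frames: int,
    seed: int,
    feature_names: list[str] | None = None,
) -> LabeledEnsemble:
    """Draw ``n_frames`` per class from its Gaussian mixture.

    ``class_specs`` maps class label → list of (mean, covariance, weight)
    triples (or :class:`MixtureComponent`).  Covariances must be positive
    definite; a scalar or 1D covariance is promoted to a diagonal matrix.
    Reproducible under ``seed``.
    """
    if len(class_specs) < 2:
        raise ValueError("need at least 2 classes")
    blocks, labels = [], []
    for ci, (label, spec) in enumerate(class_specs.items()):
        comps = _as_components(spec)
        weights = np.array([w for _, _, w in comps], dtype=float)
        if np.any(weights <= 0):
            raise ValueError(f"class {label!r}: component weights must be positive")
        weights = weights / weights.sum()
        rng = substream_rng(seed, ci)
        counts = rng.multinomial(n_frames, weights)
        rows = []
        for (mean, cov, _), n in zip(comps, counts):
            if n == 0:
                continue
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                raise ValueError(
                    f"class {label!r}: covariance is not positive definite"
                ) from None
            rows.append(mean + rng.standard_normal((n, len(mean))) @ chol.T)
        block = np.concatenate(rows, axis=0) if rows else np.empty((0, len(comps[0][0])))
        blocks.append(block)
        labels.extend([label] * block.shape[0])
    features = np.concatenate(blocks, axis=0) if blocks else np.empty((0, 0))
    return LabeledEnsemble(features, np.asarray(labels), feature_names=feature_names)
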