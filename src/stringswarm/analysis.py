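"""Supervised and unsupervised analysis of labeled conformational ensembles.

Three complementary feature-importance extractors — symmetrized
Kullback–Leibler divergence of per-class feature distributions, random-forest
mean decrease in impurity, and eigenvalue-weighted PCA loadings — plus
low-dimensional projections (PCA/MDS/t-SNE), the class-similarity matrix, and
per-residue aggregation of per-feature scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import MDS, TSNE

from .engine import substream_rng
from .ensembles import LabeledEnsemble

__all__ = [
    "ImportanceProfile",
    "ProjectionResult",
    "SimilarityMatrix",
    "kl_importance",
    "rf_importance",
    "pca_importance",
    "project",
    "class_similarity",
    "aggregate_per_residue",
]


def _parse_pair(name: str) -> tuple[str, str] | None:
    if "-" in name:
        a, b = name.split("-", 1)
        return a, b
    return None


def aggregate_per_residue(per_feature, feature_names) -> pd.Series:
    """Residue score = mean score of all features whose pair involves the
    residue.  Feature names are 'A-B' pair labels."""
    if feature_names is None:
        raise ValueError("per-residue aggregation requires feature names")
    scores = np.asarray(per_feature, dtype=float)
    if len(scores) != len(feature_names):
        raise ValueError("scores and feature_names must have equal length")
    acc: dict[str, list[float]] = {}
    for s, name in zip(scores, feature_names):
        pair = _parse_pair(str(name))
        members = pair if pair else (str(name),)
        for m in members:
            acc.setdefault(m, []).append(float(s))
    return pd.Series({k: float(np.mean(v)) for k, v in acc.items()}).sort_index()


@dataclass
class ImportanceProfile:
    """Per-feature scores (≥ 0) from one extractor, with optional per-residue
    averages when feature names carry residue pairs."""

    per_feature: np.ndarray
    method: str
    feature_names: list[str] | None = None

    def __post_init__(self):
        self.per_feature = np.asarray(self.per_feature, dtype=float)

    @property
    def per_residue(self) -> pd.Series | None:
        if self.feature_names is None:
            return None
        return aggregate_per_residue(self.per_feature, self.feature_names)

    def ranking(self) -> np.ndarray:
        """Feature indices sorted by decreasing score (stable in feature id)."""
        idx = np.arange(len(self.per_feature))
        return idx[np.lexsort((idx, -self.per_feature))]

    def to_frame(self) -> pd.DataFrame:
        names = self.feature_names or [f"f{j}" for j in range(len(self.per_feature))]
        return pd.DataFrame({"feature": names, "score": self.per_feature})


def _sturges_bins(n_frames: int, lo: int = 10, hi: int = 50) -> int:
    return int(np.clip(np.ceil(np.log2(max(n_frames, 2))) + 1, lo, hi))


def _histogram_kl(a: np.ndarray, b: np.ndarray, n_bins: int, pseudo_weight: float) -> float:
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    p = np.histogram(a, bins=edges)[0] + pseudo_weight
    q = np.histogram(b, bins=edges)[0] + pseudo_weight
    p = p / p.sum()
    q = q / q.sum()
    kl_pq = float(np.sum(p * np.log(p / q)))
    kl_qp = float(np.sum(q * np.log(q / p)))
    return 0.5 * (kl_pq + kl_qp)


def kl_importance(
    ensemble: LabeledEnsemble,
    n_bins: int | None = None,
    pseudo_weight: float = 1e-4,
    groups: dict | None = None,
) -> ImportanceProfile:
    """Symmetrized KL divergence ½[KL(p‖q) + KL(q‖p)] per feature between
    class histograms on shared bin edges.

    With more than two classes the score is the mean over unordered class
    pairs; ``groups`` (label → group) first merges classes into two groups
    (e.g. agonist vs non-agonist).  The bin count defaults to Sturges' rule
    clamped to [10, 50]; ``pseudo_weight`` smooths empty bins.
    """
    ensemble.require_supervised()
    labels = ensemble.labels
    if groups is not None:
        labels = np.asarray([groups[l] for l in labels])
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes after grouping")
    for c in classes:
        if (labels == c).sum() < 20:
            raise ValueError(f"class {c!r} has fewer than 20 frames")
    if n_bins is None:
        n_bins = _sturges_bins(ensemble.n_frames)
    X = ensemble.features
    scores = np.zeros(ensemble.n_features)
    pairs = [(a, b) for i, a in enumerate(classes) for b in classes[i + 1 :]]
    for f in range(ensemble.n_features):
        vals = [
            _histogram_kl(X[labels == a, f], X[labels == b, f], n_bins, pseudo_weight)
            for a, b in pairs
        ]
        scores[f] = float(np.mean(vals))
    return ImportanceProfile(scores, method="kl", feature_names=ensemble.feature_names)


def rf_importance(
    ensemble: LabeledEnsemble, n_trees: int = 500, seed: int = 0
) -> ImportanceProfile:
    """Random-forest mean-decrease-impurity importances (sklearn's
    normalization: scores sum to 1); deterministic under ``seed``.  The
    out-of-bag accuracy is stored on the profile as ``oob_score``."""
    ensemble.require_supervised()
    for c in ensemble.classes:
        if (ensemble.labels == c).sum() < 20:
            raise ValueError(f"class {c!r} has fewer than 20 frames")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=int(substream_rng(seed, 17).integers(0, 2**31 - 1)),
        oob_score=True,
        n_jobs=1,
    )
    clf.fit(ensemble.features, ensemble.labels)
    profile = ImportanceProfile(
        clf.feature_importances_, method="rf", feature_names=ensemble.feature_names
    )
    profile.oob_score = float(clf.oob_score_)
    return profile


def pca_importance(ensemble: LabeledEnsemble) -> ImportanceProfile:
    """Eigenvalue-weighted absolute PCA loadings, score_f = Σ_k λ_k|v_kf|,
    normalized so the top feature scores 1."""
    X = ensemble.features
    if X.shape[0] < 2:
        raise ValueError("PCA importance needs at least 2 frames")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("zero-variance feature matrix")
    pca = PCA()
    pca.fit(X)
    lam = pca.explained_variance_
    scores = np.sum(lam[:, None] * np.abs(pca.components_), axis=0)
    scores = scores / scores.max()
    return ImportanceProfile(scores, method="pca", feature_names=ensemble.feature_names)


@dataclass
class ProjectionResult:
    """Low-dimensional embedding of the frames (one row per frame)."""

    coordinates: np.ndarray
    method: str
    method_params: dict
    seed: int

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.coordinates,
            columns=[f"dim{j}" for j in range(self.coordinates.shape[1])],
        )
        df.to_csv(path, index=False, float_format="%.17g")


def project(
    ensemble: LabeledEnsemble,
    method: str = "pca",
    dims: int = 2,
    seed: int = 0,
    **params,
) -> ProjectionResult:
    """Project frames to ``dims`` dimensions with PCA (deterministic up to
    sign), metric MDS, or t-SNE (both deterministic under ``seed``)."""
    X = ensemble.features
    if X.shape[0] < dims + 1:
        raise ValueError(f"need at least {dims + 1} frames for a {dims}D projection")
    rs = int(substream_rng(seed, 19).integers(0, 2**31 - 1))
    if method == "pca":
        coords = PCA(n_components=dims).fit_transform(X)
    elif method == "mds":
        params.setdefault("init", "classical_mds")
        mds = MDS(
            n_components=dims,
            random_state=rs,
            normalized_stress=False,
            **params,
        )
        coords = mds.fit_transform(X)
    elif method == "tsne":
        params.setdefault("perplexity", min(30.0, (X.shape[0] - 1) / 3.0))
        tsne = TSNE(n_components=dims, random_state=rs, init="pca", **params)
        coords = tsne.fit_transform(X)
    else:
        raise ValueError(f"unknown projection method {method!r}")
    return ProjectionResult(np.asarray(coords, dtype=float), method, params, seed)


@dataclass
class SimilarityMatrix:
    """Class-by-class similarity in [0, 1]; symmetric, higher = more similar."""

    classes: list
    values: np.ndarray

    def similarity(self, a, b) -> float:
        i, j = self.classes.index(a), self.classes.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.classes, columns=self.classes)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, float_format="%.17g")


def class_similarity(ensemble: LabeledEnsemble, max_frames_per_class: int | None = None,
                     seed: int = 0) -> SimilarityMatrix:
    """Mean pairwise Euclidean frame distance between (and within) classes,
    min–max inverted so 1 marks the most similar entry and 0 the least.

    The diagonal uses within-class pairs and is normalized like any other
    entry.  ``max_frames_per_class`` optionally subsamples large classes for
    tractability (deterministic under ``seed``).
    """
    ensemble.require_supervised()
    classes = list(ensemble.classes)
    views = []
    rng = substream_rng(seed, 23)
    for c in classes:
        V = ensemble.class_view(c)
        if len(V) < 2:
            raise ValueError(f"class {c!r} needs at least 2 frames")
        if max_frames_per_class is not None and len(V) > max_frames_per_class:
            V = V[rng.choice(len(V), max_frames_per_class, replace=False)]
        views.append(V)
    k = len(classes)
    D = np.zeros((k, k))
    for i in range(k):
        D[i, i] = float(np.mean(pdist(views[i])))
        for j in range(i + 1, k):
            D[i, j] = D[j, i] = float(np.mean(cdist(views[i], views[j])))
    dmin, dmax = D.min(), D.max()
    if dmax == dmin:
        values = np.ones_like(D)
    else:
        values = (dmax - D) / (dmax - dmin)
    return SimilarityMatrix(classes=classes, values=values)
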