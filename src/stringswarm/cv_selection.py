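"""Data-driven CV selection: restricted Boltzmann machines ranked by
layer-wise relevance propagation (LRP).

Candidate features (min–max scaled to [0, 1]) train a small
Gaussian–Bernoulli RBM with one step of contrastive divergence (CD-1):
continuous visible units with binary hidden components, so the hidden layer
captures collective variance structure — a feature that switches between two
states pulls a hidden unit into encoding that switch.  The relevance of each
visible unit for the hidden activations is then attributed back through the
weights with the ε-rule of LRP, averaged over frames.  Because training is
stochastic, importances are averaged over many independently initialized
models, normalized so the top feature scores 1, and thresholded to give the
final CV set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cv import CVSet, FeatureSpec
from .engine import substream_rng

__all__ = ["CVSelectionConfig", "rbm_feature_importance", "select_cvs_rbm"]


@dataclass
class CVSelectionConfig:
    """Knobs of the RBM/LRP selection.

    n_hidden=2 hidden components, 50 independent models and an importance
    threshold of 0.33 are the production defaults; the 6–8 Å window is the
    upstream distance filter applied before training.  Training uses CD-1
    (sklearn's persistent contrastive divergence) with the epochs/learning
    rate below.
    """

    n_hidden: int = 2
    n_models: int = 50
    importance_threshold: float = 0.33
    distance_window: tuple[float, float] = (6.0, 8.0)
    seed: int = 0
    n_iter: int = 60
    learning_rate: float = 0.2
    batch_size: int = 32

    def __post_init__(self):
        if not 0 <= self.importance_threshold <= 1:
            raise ValueError("importance_threshold must lie in [0, 1]")
        low, high = self.distance_window
        if not low < high:
            raise ValueError("distance_window must satisfy low < high")


class _GaussianBernoulliRBM:
    """Minimal Gaussian–Bernoulli RBM trained with CD-1 minibatch SGD.

    Visible units are continuous with unit conditional variance; hidden units
    are Bernoulli.  ``components_`` has shape (n_hidden, n_features) to match
    the usual layout.
    """

    def __init__(self, n_components, learning_rate, batch_size, n_iter, rng):
        self.n_components = n_components
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_iter = n_iter
        self.rng = rng

    def _hidden_prob(self, V):
        return 1.0 / (1.0 + np.exp(-(V @ self.components_.T + self.intercept_hidden_)))

    def fit(self, X):
        n, F = X.shape
        rng = self.rng
        self.components_ = 0.01 * rng.standard_normal((self.n_components, F))
        self.intercept_hidden_ = np.zeros(self.n_components)
        self.intercept_visible_ = X.mean(axis=0).copy()
        lr = self.learning_rate
        for _ in range(self.n_iter):
            for idx in np.array_split(rng.permutation(n), max(1, n // self.batch_size)):
                V0 = X[idx]
                H0 = self._hidden_prob(V0)
                Hs = (rng.random(H0.shape) < H0).astype(float)
                # one Gibbs step: v ~ N(b + W'h, 1) in the mean-field sense
                V1 = self.intercept_visible_ + Hs @ self.components_
                H1 = self._hidden_prob(V1)
                m = len(idx)
                self.components_ += lr * (H0.T @ V0 - H1.T @ V1) / m
                self.intercept_hidden_ += lr * (H0 - H1).mean(axis=0)
                self.intercept_visible_ += lr * (V0 - V1).mean(axis=0)
        return self


def _lrp_relevance(X01: np.ndarray, rbm: _GaussianBernoulliRBM, eps: float = 1e-9) -> np.ndarray:
    """ε-rule LRP from hidden activations back to visible units, averaged over
    frames; returns one non-negative relevance per feature."""
    W = rbm.components_  # (n_hidden, F)
    h = rbm._hidden_prob(X01)  # (n, H)
    z = X01[:, None, :] * W[None, :, :]  # (n, H, F)
    denom = z.sum(axis=2)  # (n, H)
    denom = denom + eps * np.sign(denom) + (denom == 0) * eps
    R = (z / denom[:, :, None]) * h[:, :, None]  # relevance per (frame, hidden, feature)
    return np.abs(R).sum(axis=1).mean(axis=0)


def rbm_feature_importance(
    features, config: CVSelectionConfig | None = None, return_models: bool = False
):
    """Per-feature importance in [0, 1] (max normalized to 1), averaged over
    ``config.n_models`` independently seeded RBMs; deterministic under
    ``config.seed``.  With ``return_models`` also returns the per-model
    relevance matrix (n_models, n_features) before normalization."""
    if config is None:
        config = CVSelectionConfig()
    X = np.atleast_2d(np.asarray(features, dtype=float))
    n, F = X.shape
    if F < 2:
        raise ValueError("need at least 2 candidate features")
    if n < config.n_hidden * 10:
        raise ValueError(
            f"need at least {config.n_hidden * 10} frames to train "
            f"{config.n_hidden} hidden units, got {n}"
        )
    if n < 100:
        raise ValueError(f"need at least 100 frames, got {n}")
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng_range = np.where(hi > lo, hi - lo, 1.0)
    X01 = (X - lo) / rng_range
    # center the scaled features: CD then learns deviation structure and LRP
    # attributes deviations rather than offsets
    X01 = X01 - X01.mean(axis=0)
    per_model = np.empty((config.n_models, F))
    for m in range(config.n_models):
        rbm = _GaussianBernoulliRBM(
            n_components=config.n_hidden,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            n_iter=config.n_iter,
            rng=substream_rng(config.seed, 13, m),
        )
        rbm.fit(X01)
        per_model[m] = _lrp_relevance(X01, rbm)
    acc = per_model.mean(axis=0)
    top = acc.max()
    if top <= 0:
        raise RuntimeError("degenerate relevance: all features scored zero")
    if return_models:
        return acc / top, per_model
    return acc / top


def select_cvs_rbm(
    features,
    config: CVSelectionConfig | None = None,
    specs: list[FeatureSpec] | None = None,
) -> CVSet:
    """Rank features by RBM/LRP importance and return the CVs whose normalized
    importance exceeds the threshold, with global min–max bounds taken over
    the input frames.

    The returned set is ordered by decreasing importance (ties broken by
    feature id) and carries the importances as the CV weights.
    """
    if config is None:
        config = CVSelectionConfig()
    X = np.atleast_2d(np.asarray(features, dtype=float))
    importance = rbm_feature_importance(X, config)
    keep = np.flatnonzero(importance > config.importance_threshold)
    # stable order: importance descending, feature id ascending
    keep = keep[np.lexsort((keep, -importance[keep]))]
    if len(keep) == 0:
        raise RuntimeError("no feature passed the importance threshold")
    lo, hi = X.min(axis=0), X.max(axis=0)
    pad = np.where(hi > lo, 0.0, 0.5)  # constant features get unit-width bounds
    bounds = np.column_stack([lo[keep] - pad[keep], hi[keep] + pad[keep]])
    if specs is None:
        specs = [FeatureSpec(int(j), f"f{j}", transform="raw_coordinate") for j in range(X.shape[1])]
    return CVSet(
        bounds=bounds,
        importance=importance[keep],
        specs=[specs[int(j)] for j in keep],
    )
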