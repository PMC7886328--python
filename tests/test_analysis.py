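"""Ensemble analysis: KL/RF/PCA importances, projections, class similarity,
per-residue aggregation."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_score

from conftest import planted_ensemble
from stringswarm.analysis import (
    aggregate_per_residue,
    class_similarity,
    kl_importance,
    pca_importance,
    project,
    rf_importance,
)
from stringswarm.engine import substream_rng
from stringswarm.ensembles import LabeledEnsemble, generate_labeled_ensembles


class TestKLImportance:
    def test_identical_class_distributions_score_near_zero(self):
        rng = substream_rng(0, 1)
        X = rng.standard_normal((4000, 3))
        labels = np.array(["a"] * 2000 + ["b"] * 2000)
        prof = kl_importance(LabeledEnsemble(X, labels))
        assert np.all(prof.per_feature < 0.1)

    def test_shifted_gaussians_match_closed_form(self):
        """sKL of N(0, σ²) vs N(δ, σ²) is δ²/(2σ²); at δ = 2σ the histogram
        estimate must land within 15% of 2.0 for 10⁴ frames per class."""
        ens = generate_labeled_ensembles(
            {"a": [((0.0,), (1.0,), 1.0)], "b": [((2.0,), (1.0,), 1.0)]},
            10_000, seed=1,
        )
        score = kl_importance(ens).per_feature[0]
        assert score == pytest.approx(2.0, rel=0.15)

    def test_symmetric_under_class_swap(self):
        ens = planted_ensemble(2, n_noise=5)
        swapped = LabeledEnsemble(
            ens.features, np.where(ens.labels == "a", "b", "a"), ens.feature_names
        )
        assert np.allclose(kl_importance(ens).per_feature,
                           kl_importance(swapped).per_feature)

    def test_group_mode_merges_classes(self):
        n_feat = 4
        spec = {
            "ag1": [(np.r_[3.0, np.zeros(n_feat - 1)], np.ones(n_feat), 1.0)],
            "ag2": [(np.r_[3.0, np.zeros(n_feat - 1)], np.ones(n_feat), 1.0)],
            "inv": [(np.zeros(n_feat), np.ones(n_feat), 1.0)],
        }
        ens = generate_labeled_ensembles(spec, 100, seed=3)
        groups = {"ag1": "agonist", "ag2": "agonist", "inv": "other"}
        prof = kl_importance(ens, groups=groups)
        assert prof.ranking()[0] == 0

    def test_single_class_rejected(self):
        X = np.zeros((50, 2))
        ens = LabeledEnsemble(X, np.array(["a"] * 50))
        with pytest.raises(ValueError):
            kl_importance(ens)

    def test_undersampled_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((30, 2))
        ens = LabeledEnsemble(X, np.array(["a"] * 25 + ["b"] * 5))
        with pytest.raises(ValueError, match="fewer than 20"):
            kl_importance(ens)


class TestRFImportance:
    def test_pure_noise_labels_not_above_permutation_null(self):
        """With random labels the top importance must sit inside the
        permutation-null distribution."""
        rng = substream_rng(4, 0)
        X = rng.standard_normal((200, 20))
        labels = np.array(["a", "b"] * 100)
        obs = rf_importance(LabeledEnsemble(X, labels), n_trees=100, seed=0).per_feature.max()
        null = []
        for k in range(30):
            perm = substream_rng(4, k + 1).permutation(len(labels))
            null.append(
                rf_importance(LabeledEnsemble(X, labels[perm]), n_trees=100, seed=0)
                .per_feature.max()
            )
        assert obs <= np.quantile(null, 0.975)

    def test_duplicated_informative_feature_splits_importance(self):
        ens = planted_ensemble(3, n_noise=19, planted=5)
        single = rf_importance(ens, seed=3).per_feature[5]
        X = np.column_stack([ens.features, ens.features[:, 5]])
        dup = rf_importance(LabeledEnsemble(X, ens.labels), seed=3).per_feature
        combined = dup[5] + dup[20]
        assert combined >= 0.7 * single
        for share in (dup[5] / single, dup[20] / single):
            assert 0.35 <= share <= 0.65  # roughly halved, ±30%

    def test_deterministic_under_seed(self):
        ens = planted_ensemble(5, n_noise=10)
        a = rf_importance(ens, n_trees=50, seed=9).per_feature
        b = rf_importance(ens, n_trees=50, seed=9).per_feature
        assert np.array_equal(a, b)


class TestPCAImportance:
    def test_diagonal_covariance_scores_proportional_to_variance(self):
        rng = substream_rng(6, 0)
        sigmas = np.array([3.0, 1.0, 0.5, 2.0])
        X = rng.standard_normal((20_000, 4)) * sigmas
        ens = LabeledEnsemble(X, np.array(["a"] * 20_000))
        scores = pca_importance(ens).per_feature
        expected = sigmas**2 / (sigmas**2).max()
        assert np.allclose(scores, expected, atol=0.05)

    def test_single_dominant_feature_ranks_first(self):
        rng = substream_rng(6, 1)
        X = rng.standard_normal((500, 5)) * 0.01
        X[:, 2] += rng.standard_normal(500) * 10
        ens = LabeledEnsemble(X, np.array(["a"] * 500))
        assert pca_importance(ens).ranking()[0] == 2

    def test_equal_variance_correlated_pair_scores_equal(self):
        rng = substream_rng(6, 2)
        z = rng.standard_normal(1000)
        e = rng.standard_normal(1000)
        x1 = z
        x2 = 0.6 * z + 0.8 * e
        X = np.column_stack([x1, x2])
        X = np.vstack([X, X[:, ::-1]])  # exact swap symmetry of the sample
        ens = LabeledEnsemble(X, np.array(["a"] * 2000))
        scores = pca_importance(ens).per_feature
        assert abs(scores[0] - scores[1]) < 1e-6

    def test_zero_variance_matrix_rejected(self):
        ens = LabeledEnsemble(np.ones((10, 3)), np.array(["a"] * 10))
        with pytest.raises(ValueError, match="zero-variance"):
            pca_importance(ens)


class TestProjections:
    def test_pca_component_aligns_with_variance_axis(self):
        rng = substream_rng(7, 0)
        X = np.zeros((200, 3))
        X[:, 1] = rng.standard_normal(200) * 5
        X += rng.standard_normal((200, 3)) * 0.01
        ens = LabeledEnsemble(X, np.array(["a"] * 200))
        from sklearn.decomposition import PCA

        pca = PCA(n_components=1).fit(ens.features)
        assert abs(pca.components_[0][1]) > 0.999
        coords = project(ens, "pca", dims=2).coordinates
        assert coords.shape == (200, 2)

    def test_mds_recovers_exact_low_dimensional_geometry(self):
        rng = substream_rng(7, 1)
        P2 = rng.standard_normal((40, 2))
        Q = np.linalg.qr(rng.standard_normal((10, 10)))[0][:, :2]
        X = P2 @ Q.T  # isometric embedding of a 2D point set in 10D
        ens = LabeledEnsemble(X, np.array(["a"] * 20 + ["b"] * 20))
        res = project(ens, "mds", dims=2, seed=0, max_iter=500)
        d0, d1 = pdist(P2), pdist(res.coordinates)
        stress = np.sum((d0 - d1) ** 2) / np.sum(d0**2)
        assert stress < 1e-6

    def test_tsne_separates_well_separated_classes(self):
        means = {c: [(np.r_[np.eye(3)[i] * 20, np.zeros(2)], np.ones(5), 1.0)]
                 for i, c in enumerate("abc")}
        ens = generate_labeled_ensembles(means, 60, seed=2)
        res = project(ens, "tsne", dims=2, seed=0)
        assert silhouette_score(res.coordinates, ens.labels) > 0.5

    def test_seeded_projections_reproducible(self):
        ens = planted_ensemble(8, n_noise=5, n_frames=40)
        a = project(ens, "tsne", dims=2, seed=3).coordinates
        b = project(ens, "tsne", dims=2, seed=3).coordinates
        assert np.array_equal(a, b)

    def test_unknown_method_rejected(self):
        ens = planted_ensemble(8, n_noise=3, n_frames=30)
        with pytest.raises(ValueError, match="unknown projection"):
            project(ens, "umap")


class TestClassSimilarity:
    def test_identically_distributed_pair_most_similar(self):
        spec = {
            "a": [((0.0, 0.0), np.eye(2), 1.0)],
            "b": [((0.0, 0.0), np.eye(2), 1.0)],
            "c": [((8.0, 8.0), np.eye(2), 1.0)],
        }
        ens = generate_labeled_ensembles(spec, 150, seed=4)
        sim = ens and class_similarity(ens)
        off = [(sim.similarity(x, y), (x, y)) for x, y in [("a", "b"), ("a", "c"), ("b", "c")]]
        assert max(off)[1] == ("a", "b")

    def test_collinear_centroids_ordering_strict(self):
        spec = {
            "x0": [((0.0,), (0.001,), 1.0)],
            "x1": [((1.0,), (0.001,), 1.0)],
            "x10": [((10.0,), (0.001,), 1.0)],
        }
        ens = generate_labeled_ensembles(spec, 50, seed=5)
        sim = class_similarity(ens)
        assert sim.similarity("x0", "x1") > sim.similarity("x0", "x10")

    def test_normalization_attains_zero_and_one(self):
        ens = planted_ensemble(6, n_noise=3)
        sim = class_similarity(ens)
        assert sim.values.min() == 0.0
        assert sim.values.max() == 1.0
        assert np.array_equal(sim.values, sim.values.T)
        assert np.all((sim.values >= 0) & (sim.values <= 1))

    def test_class_with_single_frame_rejected(self):
        X = np.random.default_rng(0).standard_normal((5, 2))
        ens = LabeledEnsemble(X, np.array(["a"] * 4 + ["b"]))
        with pytest.raises(ValueError, match="at least 2 frames"):
            class_similarity(ens)


class TestPerResidue:
    def test_single_feature_scores_both_members(self):
        out = aggregate_per_residue([1.0], ["A-B"])
        assert out["A"] == 1.0 and out["B"] == 1.0

    def test_mean_over_incident_features(self):
        out = aggregate_per_residue([1.0, 0.0], ["A-B", "A-C"])
        assert out["A"] == 0.5 and out["B"] == 1.0 and out["C"] == 0.0

    def test_five_residue_network_matches_hand_computation(self):
        names = ["R1-R2", "R1-R3", "R2-R3", "R3-R4", "R4-R5"]
        scores = [0.8, 0.4, 0.6, 0.2, 1.0]
        out = aggregate_per_residue(scores, names)
        assert out["R1"] == pytest.approx(0.6)       # (0.8+0.4)/2
        assert out["R2"] == pytest.approx(0.7)       # (0.8+0.6)/2
        assert out["R3"] == pytest.approx(0.4)       # (0.4+0.6+0.2)/3
        assert out["R4"] == pytest.approx(0.6)       # (0.2+1.0)/2
        assert out["R5"] == pytest.approx(1.0)

    def test_missing_names_rejected(self):
        with pytest.raises(ValueError, match="feature names"):
            aggregate_per_residue([1.0], None)


class TestCrossMethod:
    def test_all_methods_rank_planted_feature_first(self):
        """Concordance of KL, RF and PCA importance on planted-signal data."""
        ens = planted_ensemble(9, n_noise=30, planted=4)
        assert kl_importance(ens).ranking()[0] == 4
        assert rf_importance(ens, n_trees=200, seed=9).ranking()[0] == 4
        assert pca_importance(ens).ranking()[0] == 4

    def test_importances_nonnegative_and_permutation_equivariant(self):
        ens = planted_ensemble(10, n_noise=6, planted=2)
        perm = np.array([3, 0, 5, 1, 6, 2, 4])
        permuted = LabeledEnsemble(ens.features[:, perm], ens.labels)
        for fn in (kl_importance, pca_importance):
            a = fn(ens).per_feature
            b = fn(permuted).per_feature
            assert np.all(a >= 0)
            assert np.allclose(b, a[perm], atol=1e-10)
        # RF: permutation changes tree randomization; the winner must follow
        rf_p = rf_importance(permuted, n_trees=200, seed=10)
        assert rf_p.ranking()[0] == int(np.flatnonzero(perm == 2)[0])
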