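"""Transition-matrix free-energy estimation, ΔG, expectation values and the
efficacy regression."""

import numpy as np
import pytest
from scipy import integrate, stats

from stringswarm.cv import identity_cvset
from stringswarm.engine import EngineParams, propagate, substream_rng
from stringswarm.free_energy import (
    BasinDef,
    GridSpec,
    boltzmann_invert,
    count_transitions,
    delta_g,
    estimate_transition_matrix,
    expectation_value,
    fit_efficacy,
    implied_timescales,
    posterior_surfaces,
    predict_efficacy,
)
from stringswarm.potentials import DoubleWell1D


class TestGridAndCounts:
    def test_self_transitions_accumulate_on_diagonal(self):
        grid = GridSpec.regular([0.0], [5.0], [5])
        x = np.full((10, 1), 3.1)  # bin 3
        counts, dropped = count_transitions(x, x, grid)
        assert counts[3, 3] == 10
        assert counts.sum() == 10
        assert dropped == 0

    def test_hand_listed_transitions_on_three_bins(self):
        grid = GridSpec.regular([0.0], [3.0], [3])
        pairs = [(0, 1), (1, 2), (2, 2), (1, 0), (0, 0), (2, 1)]
        starts = np.array([[i + 0.5] for i, _ in pairs])
        ends = np.array([[j + 0.5] for _, j in pairs])
        counts, _ = count_transitions(starts, ends, grid)
        expected = np.array([[1, 1, 0], [1, 0, 1], [0, 1, 1]], dtype=float)
        assert np.array_equal(counts, expected)

    def test_out_of_grid_pairs_dropped_and_tallied(self):
        grid = GridSpec.regular([0.0], [1.0], [2])
        starts = np.array([[0.5], [5.0]])
        ends = np.array([[0.5], [0.5]])
        counts, dropped = count_transitions(starts, ends, grid)
        assert dropped == 1
        assert counts.sum() == 1

    def test_all_transitions_outside_grid_rejected(self):
        grid = GridSpec.regular([0.0], [1.0], [2])
        with pytest.raises(ValueError, match="outside the grid"):
            count_transitions(np.array([[9.0]]), np.array([[9.0]]), grid)

    def test_zero_count_matrix_refused_by_estimator(self):
        with pytest.raises(ValueError, match="no transitions"):
            estimate_transition_matrix(np.zeros((3, 3)))


class TestTransitionMatrix:
    def test_symmetric_two_bin_counts_give_uniform_stationary(self):
        model = estimate_transition_matrix(np.array([[5.0, 5.0], [5.0, 5.0]]))
        assert np.allclose(model.stationary, [0.5, 0.5], atol=1e-12)

    def test_two_state_closed_forms(self):
        """π of a 2-state chain is (T21, T12)/(T12+T21)."""
        m1 = estimate_transition_matrix(np.array([[9.0, 1.0], [1.0, 9.0]]), pseudo_count=0)
        assert np.allclose(m1.stationary, [0.5, 0.5], atol=1e-12)
        m2 = estimate_transition_matrix(np.array([[8.0, 2.0], [1.0, 9.0]]), pseudo_count=0)
        assert np.allclose(m2.stationary, [1 / 3, 2 / 3], atol=1e-12)

    def test_stationary_is_fixed_point(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 50, (6, 6)).astype(float)
        model = estimate_transition_matrix(counts)
        assert np.allclose(model.stationary @ model.transition_matrix,
                           model.stationary, atol=1e-10)
        assert np.allclose(model.transition_matrix.sum(axis=1), 1.0, atol=1e-10)

    def test_disconnected_bins_restricted_with_warning(self):
        counts = np.zeros((4, 4))
        counts[:2, :2] = [[5, 5], [5, 5]]
        counts[2, 3] = 1  # one-way edge: bins 2, 3 not strongly connected
        with pytest.warns(UserWarning, match="dropped"):
            model = estimate_transition_matrix(counts)
        assert set(model.active_bins.tolist()) == {0, 1}

    def test_reversible_estimate_satisfies_detailed_balance(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(5, 60, (6, 6)).astype(float)
        model = estimate_transition_matrix(counts, reversible=True)
        pi, T = model.stationary, model.transition_matrix
        flux = pi[:, None] * T
        assert np.allclose(flux, flux.T, atol=1e-8)
        assert np.allclose(pi @ T, pi, atol=1e-8)

    def test_reversible_agrees_with_rowwise_on_balanced_counts(self):
        """On counts that already satisfy detailed balance the two estimators
        coincide."""
        pi_true = np.array([0.5, 0.3, 0.2])
        T = np.array([[0.8, 0.15, 0.05], [0.25, 0.65, 0.1], [0.125, 0.15, 0.725]])
        counts = 10_000 * pi_true[:, None] * T  # exact detailed-balanced flux
        rowwise = estimate_transition_matrix(counts, pseudo_count=0)
        rev = estimate_transition_matrix(counts, pseudo_count=0, reversible=True)
        assert np.allclose(rowwise.stationary, pi_true, atol=1e-8)
        assert np.allclose(rev.stationary, pi_true, atol=1e-6)

    def test_stationary_invariant_to_bin_relabeling(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 30, (5, 5)).astype(float)
        model = estimate_transition_matrix(counts)
        perm = rng.permutation(5)
        permuted = counts[np.ix_(perm, perm)]
        model_p = estimate_transition_matrix(permuted)
        assert np.allclose(model_p.stationary, model.stationary[perm], atol=1e-10)


class TestBoltzmannInversion:
    def test_uniform_distribution_gives_flat_landscape(self):
        F = boltzmann_invert(np.full(4, 0.25))
        assert np.allclose(F.F, 0.0)

    def test_closed_form_free_energy_difference(self):
        F = boltzmann_invert(np.array([0.8, 0.2]), kT=1.0)
        assert F.F[0] == 0.0
        assert F.F[1] == pytest.approx(np.log(4.0))

    def test_doubling_kT_doubles_differences(self):
        pi = np.array([0.7, 0.2, 0.1])
        F1, F2 = boltzmann_invert(pi, kT=1.0), boltzmann_invert(pi, kT=2.0)
        assert np.allclose(F2.F, 2 * F1.F)

    def test_zero_probability_bin_marked_unbounded(self):
        F = boltzmann_invert(np.array([0.5, 0.5, 0.0]))
        assert np.isinf(F.F[2])
        assert np.isfinite(F.F[:2]).all()


class TestPosterior:
    @staticmethod
    def chain_counts(scale=1.0):
        n = 8
        counts = np.zeros((n, n))
        for i in range(n):
            counts[i, i] = 100
            if i > 0:
                counts[i, i - 1] = 30 + 4 * i
            if i < n - 1:
                counts[i, i + 1] = 30 + 2 * i
        return counts * scale

    def test_stderr_shrinks_tenfold_when_counts_scale_hundredfold(self):
        F1 = posterior_surfaces(self.chain_counts(), n_samples=400, seed=1)
        F2 = posterior_surfaces(self.chain_counts(100), n_samples=400, seed=1)
        ratios = F1.stderr / F2.stderr
        assert np.all((ratios > 7) & (ratios < 13))

    def test_single_sample_stderr_undefined(self):
        with pytest.warns(UserWarning, match="stderr undefined"):
            F = posterior_surfaces(self.chain_counts(), n_samples=1, seed=0)
        assert np.isnan(F.stderr).all()

    def test_two_bin_posterior_mean_matches_independent_beta_oracle(self):
        """Oracle: π₁ = T₂₁/(T₁₂+T₂₁) with independent Beta-posterior row
        draws, sampled directly with scipy — independent of the eigenvector
        path used by the estimator."""
        counts = np.array([[40.0, 10.0], [5.0, 45.0]])
        alpha = 0.5  # pseudo-count
        F = posterior_surfaces(counts, n_samples=800, seed=2, pseudo_count=alpha)
        rng = np.random.default_rng(1234)
        t12 = rng.beta(10 + alpha, 40 + alpha, 20000)
        t21 = rng.beta(5 + alpha, 45 + alpha, 20000)
        pi0 = t21 / (t12 + t21)
        F_oracle = -np.log(np.column_stack([pi0, 1 - pi0]))
        dF_oracle = F_oracle[:, 1] - F_oracle[:, 0]
        dF_est = F.F[1] - F.F[0]
        se = dF_oracle.std() / np.sqrt(800)  # MC error at the estimator's n
        assert abs(dF_est - dF_oracle.mean()) < 3 * se

    def test_posterior_mean_converges_to_point_estimate(self):
        counts = self.chain_counts(100)
        model = estimate_transition_matrix(counts)
        F_point = boltzmann_invert(model.stationary)
        F_post = posterior_surfaces(counts, n_samples=300, seed=3)
        assert np.allclose(F_post.F, F_point.F, atol=0.02)


class TestExpectationAndDeltaG:
    def test_constant_observable_returns_constant(self):
        assert expectation_value(np.full(5, 5.0), np.full(5, 0.2)) == pytest.approx(5.0)

    def test_two_bin_average(self):
        assert expectation_value([0.0, 2.0], [0.5, 0.5]) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            expectation_value([1.0], [0.5, 0.5])

    def test_msm_expectation_matches_long_run_time_average(self):
        """Ergodic oracle: ⟨x⟩ from the swarm-MSM stationary distribution vs
        the time average of a long unbiased trajectory."""
        pot = DoubleWell1D(barrier=2.0, tilt=0.8)
        p = EngineParams(timestep=5e-3, seed=31)
        rng = substream_rng(31, 0)
        X = np.full((50, 1), -1.0)
        X = propagate(X, pot, p, 4000, rng)
        samples = []
        grid = GridSpec.regular([-1.6], [1.6], [24])
        all_starts, all_ends = [], []
        for _ in range(60):
            X0 = X.copy()
            X = propagate(X, pot, p, 200, rng)
            all_starts.append(X0)
            all_ends.append(X)
            samples.append(X[:, 0].copy())
        samples = np.concatenate(samples)
        counts, _ = count_transitions(np.concatenate(all_starts), np.concatenate(all_ends), grid)
        model = estimate_transition_matrix(counts)
        centers = grid.centers[model.active_bins][:, 0]
        msm_avg = expectation_value(centers, model.stationary)
        sem = samples.std() / np.sqrt(len(samples) / 40)  # generous correlation factor
        assert abs(msm_avg - samples.mean()) < 3 * sem

    def test_delta_g_antisymmetry(self):
        pi = np.array([0.1, 0.3, 0.4, 0.2])
        a = np.array([True, True, False, False])
        b = ~a
        assert delta_g(pi, a, b) == pytest.approx(-delta_g(pi, b, a))

    def test_symmetric_double_well_delta_g_zero(self):
        pot = DoubleWell1D(barrier=2.0, tilt=0.0)
        grid = GridSpec.regular([-1.5], [1.5], [30])
        centers = grid.centers[:, 0]
        pi = np.exp(-pot.energy(grid.centers))
        pi /= pi.sum()
        dg = delta_g(pi, centers < 0, centers > 0)
        assert abs(dg) < 1e-10

    def test_delta_g_invariant_to_bin_refinement(self):
        pot = DoubleWell1D(barrier=2.0, tilt=1.11)
        split = pot.known_saddles[0][0]
        vals = []
        for nb in (30, 60):
            grid = GridSpec.regular([-2.0], [2.0], [nb])
            c = grid.centers[:, 0]
            pi = np.exp(-pot.energy(grid.centers))
            pi /= pi.sum()
            vals.append(delta_g(pi, c < split, c > split))
        assert abs(vals[0] - vals[1]) < 0.05

    def test_basin_validation(self):
        pi = np.array([0.5, 0.5])
        with pytest.raises(ValueError, match="disjoint"):
            delta_g(pi, [True, True], [False, True])
        with pytest.raises(ValueError, match="at least one bin"):
            delta_g(pi, [False, False], [True, True])
        with pytest.warns(UserWarning, match="zero probability"):
            out = delta_g(np.array([0.0, 1.0]), [True, False], [False, True])
        assert np.isinf(out)

    def test_basin_box_predicate(self):
        centers = np.array([[-1.0], [0.0], [1.0]])
        basin = BasinDef.box("left", [-1.5], [-0.5])
        assert basin.mask(centers).tolist() == [True, False, False]


class TestEfficacyRegression:
    def test_noiseless_linear_data_recovered_exactly(self):
        x = np.array([0.1, 0.4, 0.5, 0.8, 1.0])
        y = -100.0 * x + 30.0
        model = fit_efficacy(x, y)
        assert model.pearson_r == pytest.approx(-1.0)
        assert model.slope == pytest.approx(-100.0)
        assert model.intercept == pytest.approx(30.0)

    def test_slope_recovered_within_sampling_distribution(self):
        """OLS oracle: over 100 seeded noisy datasets the true slope lies
        within 3 reported standard errors in the vast majority of fits."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 1, 5)
            y = -100.0 * x + 30.0 + rng.normal(0, 5, 5)
            try:
                m = fit_efficacy(x, y)
            except ValueError:
                continue
            hits += abs(m.slope + 100.0) < 3 * m.stderr
        assert hits >= 95

    def test_constant_emax_flagged(self):
        with pytest.warns(UserWarning, match="correlation undefined"):
            m = fit_efficacy([0.1, 0.5, 0.9], [2.0, 2.0, 2.0])
        assert m.slope == 0.0
        assert np.isnan(m.pearson_r)

    def test_zero_variance_expectations_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_efficacy([0.5, 0.5, 0.5], [1.0, 2.0, 3.0])

    def test_prediction_at_mean_x_returns_mean_y(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 6)
        y = 3 * x + rng.normal(0, 1, 6)
        m = fit_efficacy(x, y)
        yhat, _ = predict_efficacy(m, x.mean())
        assert yhat == pytest.approx(y.mean())

    def test_holdout_prediction_exact_on_noiseless_line(self):
        """Hold one ligand out of a noiseless linear table and infer its
        efficacy from the fit — exact recovery."""
        x = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        y = 50.0 * x + 7.0
        m = fit_efficacy(x[:-1], y[:-1])
        yhat, (lo, hi) = predict_efficacy(m, x[-1])
        assert yhat == pytest.approx(y[-1], abs=1e-10)

    def test_fewer_than_three_ligands_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_efficacy([0.1, 0.2], [1.0, 2.0])


def test_implied_timescales_flat_for_markovian_chain():
    counts = TestPosterior.chain_counts(10)
    its = implied_timescales(counts, lags=[1, 2, 4])
    t2 = [t for _, t in its]
    assert np.isfinite(t2).all()
    # powers of a true Markov matrix give exactly flat implied timescales
    assert max(t2) / min(t2) < 1.01
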