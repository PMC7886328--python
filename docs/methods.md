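# Methods

`stringswarm` implements an enhanced-sampling and analysis stack for
conformational transitions — the string method with swarms of trajectories,
an adaptive kinetically-trapped state sampler, transition-matrix free-energy
estimation with Bayesian error bars, RBM-based collective-variable selection,
and supervised/unsupervised feature-importance analysis — exercised end to
end on analytic toy dynamics, so that every algorithmic claim can be checked
against closed-form or brute-force truth.

## Toy dynamics in place of molecular dynamics

The propagator is overdamped (Brownian) Euler–Maruyama dynamics,

    x(t+Δt) = x(t) − (D Δt / kT) ∇U(x) + sqrt(2 D Δt) ξ,

which is ergodic for the Boltzmann density of any confining analytic
potential. Any ergodic sampler of exp(−U/kT) suffices for the algorithms
under study; this is the simplest correct choice. All units are reduced:
kT = 1, D = 1, and the timestep (default 1e-3) is chosen so that the
stiffest curvature satisfies κDΔt/kT ≪ 1. The discretization error of the
invariant measure at these settings was measured on the tilted double well:
a brute-force long run reproduces the quadrature ΔG within 0.04 kT, an
order of magnitude below the tolerances used anywhere else.

Randomness is organised as one counter-based substream per (seed, stage,
index), so results cannot depend on execution order and identical seeds are
bit-reproducible.

Bundled potentials: harmonic wells, tilted quartic double wells
U = h(x²−1)² + a·x (the tilt a = 1.11 at h = 2 gives basin populations
0.880/0.120 by quadrature, i.e. ΔG ≈ −1.99 kT — the asymmetric benchmark),
the Müller–Brown surface (scaled by 0.05 so barriers are a few kT), and
Gaussian-mixture landscapes. Stationary points are stored to ~1e-8 and
re-refined numerically in tests.

## CV space

The samplers operate in *weighted scaled CV space*: each collective variable
is min–max scaled to be unitless over its bounds, then multiplied by an
importance weight in (0, 1]. All distances, drifts and restraint forces are
Euclidean in that space, so important degrees of freedom dominate the
metric. Restraint force constants are the base constant (default 3366
energy/length²) times each CV's importance. For molecular-style features the
package supports inverse inter-residue distances with a 6–8 Å
sampled-range filter; the permissive reading (a feature is kept if *any*
frame lies in-window) is the default, a quantile-based stricter variant is
exposed. Scaling bounds are global over the dataset, not per-iteration.

## CV selection: Gaussian–Bernoulli RBM + layer-wise relevance propagation

Candidate features (min–max scaled, then centered) train a small restricted
Boltzmann machine with continuous visible units and 2 Bernoulli hidden
components, via one-step contrastive divergence (CD-1) minibatch SGD
(learning rate 0.2, 60 epochs, batch 32). Continuous visible units matter:
with Bernoulli visible units CD receives no usable gradient from
continuous-valued features and the weights never break symmetry. With the
Gaussian–Bernoulli energy the hidden units align with the dominant
covariance structure, so a feature that switches between two states pulls a
hidden unit into encoding the switch.

Feature relevance is attributed from the hidden activations back to the
visible units with the ε-rule of layer-wise relevance propagation, averaged
over frames, then averaged over 50 independently initialized models (training
is stochastic), normalized so the top feature scores exactly 1, and
thresholded at 0.33. Ranking ties break by feature id. On planted data (one
bimodal feature among unit-variance noise) the planted feature ranks first
in every 50-model average and in ≥ 46/50 individual models across 20
datasets.

## String method with swarms of trajectories

A string of n points (default 20–25) connects two states in weighted CV
space. Per iteration, each point is re-equilibrated under a harmonic
restraint (30 steps by default; the final frame is the swarm launch point),
a swarm of 16–32 short unbiased trajectories (20 steps) is launched, and the
point moves by the swarm's mean displacement — the drift, proportional to
minus the free-energy gradient times a mobility. Swarm size is adaptive:
batches of trajectories are added until the standard error of the drift
(root of summed componentwise variances of the mean) falls below the drift
tolerance, or the cap of 32 is reached. A failed walker marks its record
failed; the point keeps its position for that iteration.

Reparametrization resamples the string to equal arc length in the weighted
metric, iterated until consecutive segment lengths agree within 1e-9 (one
pass leaves unequal chords where a kink falls between samples). Endpoints
are held fixed by default; a free-endpoint mode exists. Because the
converged string diffuses around the equilibrium path, convergence is judged
on strings averaged over a trailing window (default 60 iterations): the run
is converged when the RMS point distance between the means of two
consecutive windows drops below tolerance. The default protocol constants —
305 iterations maximum, swarms of 16–32, averaging window 60, base force
constant 3366 — are the package defaults so the production protocol is the
default protocol; toy studies use far fewer iterations (the Müller–Brown
benchmark converges through both saddles in ≈ 200 iterations, the 1D double
well in ≈ 100).

All per-point propagation is batched into single vectorized array
operations, so a full iteration costs a few dozen numpy calls regardless of
the number of points.

Simulation-budget accounting (steered time + restrained equilibrations +
swarms, reported in µs to two decimals) uses exact decimal arithmetic, so
it is platform-independent.

## Kinetically trapped state sampling

A fixed ensemble of 24 walkers starts from one configuration. Each
iteration propagates all walkers (7.5 ns in the molecular setting; 150 toy
steps by default), computes the endpoint center c (mean in weighted CV
space) and spread d (mean endpoint-to-center distance), assigns each walker
w_i = exp(−(|x_i − c|/d)²), and reseeds n_i ∝ w_i/Σw_j copies of each
endpoint with Σn_i = 24 by largest-remainder rounding (ties to the lower
index). Degenerate d = 0 falls back to uniform weights. Convergence is
monitored through |c_t − c_{t−1}|; eight iterations suffice on all bundled
systems. Because walkers are only ever *selected*, never pushed, the
ensemble cannot cross barriers it would not cross spontaneously — on a
10 kT double well, 20 × 8 × 24 walker-iterations produce zero crossings —
which is precisely the intended "most stabilized kinetically accessible
state" semantics. A seeded three-way split of the walkers supports
cross-validation of per-state statistics.

## Free energy from swarm transitions

Swarm (start → end) pairs at a fixed lag are binned on a grid; counts plus a
pseudo-count (default 1/n_bins per element) are row-normalized over the
largest strongly connected bin set (dropped bins are reported), and the
stationary distribution π of the resulting matrix is converted to free
energy by Boltzmann inversion F = −kT ln π, min-shifted to zero. Uncertainty
comes from 1000 transition matrices drawn from the row-wise Dirichlet
posterior of the counts; the per-bin sample standard deviation of F is the
reported error bar, and it concentrates at the expected ×10 rate when counts
grow ×100.

Two estimation modes exist. The default row-wise estimator makes no
reversibility assumption. For quantities that difference probabilities
*across* a barrier (basin ΔG), the detailed-balance-constrained maximum-
likelihood estimate (the standard self-consistent iteration on symmetrized
counts) is preferred: the row-wise estimate accumulates the noise of every
forward/backward count ratio along the chain of bins crossing the barrier,
which produced a systematic ~0.1 kT shortfall of |ΔG| at the sampling sizes
used here, while the reversible estimate removes it. The ΔG benchmark
protocol therefore uses lag-40 production swarms, a grid whose bin width
(0.05) matches the restrained-start width, reversible estimation, and a mean
over three independent replicas; it recovers the quadrature ΔG ≈ −1.99 kT
within 0.03–0.11 kT across unrelated seeds (tolerance 0.2 kT).

Microswitch expectation values are ⟨s⟩ = Σ s_b π_b on the marginal grid of
the observable (a joint-grid route is available through multi-variable
grids). ΔG between named basins is −kT ln of the ratio of summed stationary
probabilities; basins are explicit rectangular predicates (for toy systems,
the analytic watershed at the saddle), disjoint by construction. An
implied-timescale diagnostic (t₂ vs lag) is provided for checking the
Markov assumption at the swarm length used; no specific behavior is claimed
beyond the diagnostic itself.

The efficacy stage fits ordinary least squares between per-ligand
expectation values and experimental Emax (Pearson r reported), and predicts
held-out ligands from the fitted line with a t-based prediction interval
from the residual variance. It is validated on synthetic linear tables,
including exact hold-one-out recovery; no receptor-specific correlation
values are claimed, since those require all-atom ensembles and external
pharmacology data.

## Ensemble analysis

Labeled ensembles (frames × features, one class per "ligand") are analysed
with three importance extractors: (i) symmetrized KL divergence
½[KL(p‖q)+KL(q‖p)] of per-class histograms on shared edges (Sturges bin
count clamped to [10, 50], pseudo-weight 1e-4 per bin; multi-class scores
average over unordered class pairs, with an optional two-group mode such as
agonist vs non-agonist); (ii) random-forest mean decrease in impurity
(500 trees, √F features per split, full-data training with the out-of-bag
score logged); (iii) PCA importance Σ_k λ_k|v_kf| normalized to max 1.
Per-residue scores are the mean over features incident to the residue.
Projections (PCA, metric MDS with classical-MDS initialization, t-SNE with
perplexity ≤ 30) and a class-similarity matrix (mean pairwise Euclidean
frame distance, min–max inverted so 1 = most similar, diagonal included in
the normalization) complete the module. t-SNE layouts are parametrization-
dependent, so tests assert only class separation, never geometry.

## What the synthetic data does and does not show

The generator draws each class from a Gaussian mixture with planted,
closed-form differences (mean shifts in known coordinates, bimodal state
switches). This validates *recovery*: that each method finds exactly the
structure put in, at known signal-to-noise. Real molecular ensembles differ
in ways the mixtures do not emulate — correlated features, heavy tails,
slow within-state dynamics, frames that stray outside the labeled state —
so passing tests certify algorithmic correctness and statistical power on
idealized inputs, not performance on any specific receptor system.
Similarly, the toy dynamics engine shares the Boltzmann target and the
timescale separation (short swarms vs slow transitions) with molecular
simulation but none of its dimensionality.

## Problem sizes

Benchmark runs were sized for a single CPU: the 1D Boltzmann-recovery and
ΔG studies use strings of 24 points run for 100 iterations followed by
~1–2×10⁵ production swarm trajectories; the Müller–Brown path uses 25 points
for 220 iterations; planted-feature recovery uses 100 datasets of 2×200
frames × 51 features; the posterior-concentration study uses 1000 posterior
samples on a 10-bin chain. Each completes in seconds to a couple of
minutes; results quoted in the README were produced at exactly these sizes.

## Known limitations

- The equal-arc-length reparametrization slightly smooths kinks; strings
  cannot represent cusps in the minimum free-energy path.
- The row-wise Markov estimator inherits lag bias: barrier tops are
  systematically shallowed by ~0.2 kT at lag 20 on the bundled double well
  (well inside the 0.3 kT acceptance band, and reduced at longer lags).
- The string method finds one transition path; systems with competing
  channels need multiple runs from different initial paths (both endpoints
  can serve as the starting side).
- Kinetically-trapped sampling is by design not an equilibrium sampler
  across barriers; its statistics describe only the basin it occupies.
- The RBM selector assumes the informative features show variance or state
  structure visible to a two-hidden-unit model; deeply nonlinear collective
  modes may require more hidden units (configurable).
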