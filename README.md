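# stringswarm

Enhanced-sampling and data-driven analysis of conformational transitions:
the string method with swarms of trajectories, adaptive kinetically-trapped
state sampling, transition-matrix free-energy estimation, RBM-based
collective-variable selection, and feature-importance analysis of labeled
conformational ensembles — implemented as a tested library + CLI and
exercised on analytic toy dynamics with closed-form ground truth.

The package is written for method developers and simulation practitioners
who want these algorithms as verifiable, reusable components: every stage
that in production would consume molecular-dynamics trajectories (of, say, a
G-protein-coupled receptor activating under different ligands) here runs on
Brownian dynamics over analytic potentials, so the whole pipeline is
testable against quadrature, numeric optimization, and planted-signal
constructions.

## The methods

**String method with swarms of trajectories.** An ordered path of points in
importance-weighted CV space connects two states. Per iteration, each point
is re-equilibrated under a harmonic restraint, a swarm of 16–32 short
unbiased trajectories is launched from it, and the point moves by the
swarm's mean displacement — the *drift*, proportional to −∇F times a
mobility — before the string is reparametrized to equal arc length. The
string relaxes onto the most probable transition path; convergence is judged
on strings averaged over a trailing 60-iteration window.

**Kinetically trapped state sampling.** A fixed set of 24 walkers is
iteratively reseeded around its own center: after each round of propagation
the center c and spread d of the endpoints define weights
w_i = exp(−(|x_i − c|/d)²), and n_i ∝ w_i/Σw_j copies of each walker are
extended, keeping the total fixed. The ensemble settles into — and then
diffuses around — the most stabilized state kinetically accessible from the
start, without ever being forced across a barrier.

**Free energy and efficacy.** Swarm transitions binned on a grid give a
regularized transition matrix T; Boltzmann inversion of its stationary
distribution, F = −kT ln π, yields the free-energy surface, with error bars
from 1000 matrices sampled from the Dirichlet posterior of the counts. Basin
free-energy differences ΔG = −kT ln(Σ_A π/Σ_B π) and observable expectation
values ⟨s⟩ = Σ s_b π_b feed a linear regression against experimental
efficacy (Emax), which predicts the efficacy of held-out ligands.

**CV selection and ensemble analysis.** Candidate features are ranked by
layer-wise relevance propagation through Gaussian–Bernoulli restricted
Boltzmann machines (averaged over 50 models, thresholded at 0.33). Labeled
per-ligand ensembles are compared with symmetrized Kullback–Leibler
divergence, random-forest impurity importance and PCA loadings (with
per-residue aggregation), projected with PCA/MDS/t-SNE, and summarized in a
class-similarity matrix.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

Recover the free-energy landscape and basin ΔG of an asymmetric double well
(quadrature populations 0.88/0.12) from string + swarm sampling alone:

```python
import numpy as np
from stringswarm import (
    EngineParams, GridSpec, StringConfig, StringSampler,
    boltzmann_invert, count_transitions, estimate_transition_matrix,
    delta_g, identity_cvset, initialize_path,
)
from stringswarm.potentials import DoubleWell1D
from stringswarm.pipeline import analytic_reference, fes_rmsd

pot = DoubleWell1D(barrier=2.0, tilt=1.11)   # left basin holds 88%
cv = identity_cvset([[-1.6, 1.6]])
params = EngineParams(timestep=1e-3, seed=7)
cfg = StringConfig(n_points=24, swarm_len=40)

path = initialize_path(cv.to_weighted(np.asarray(pot.known_minima)[[0, -1]]), 24)
sampler = StringSampler(pot, cv, path, cfg, params)
sampler.run(100)                               # string relaxation
starts, ends = sampler.production_swarms(130)  # ~1e5 swarm trajectories

grid = GridSpec.regular([-1.5], [1.5], [60])
counts, _ = count_transitions(starts, ends, grid)
model = estimate_transition_matrix(counts, reversible=True)
fes = boltzmann_invert(model.stationary, bin_centers=grid.centers[model.active_bins])

split = pot.known_saddles[0][0]
centers = fes.bin_centers[:, 0]
print(delta_g(model.stationary, centers < split, centers > split))
print(fes_rmsd(fes.F, analytic_reference(pot, grid)[model.active_bins]))
```

Output at these sizes:

```
swarm trajectories used : 99840
barrier height (est.)   : 3.06 kT
ΔG(left, right)         : -2.03 kT   (quadrature: -1.99 kT)
FES RMSD vs Boltzmann   : 0.145 kT (bins below 4 kT)
```

The ΔG estimate lands within 0.04 kT of the quadrature value −1.99 kT, and
the full profile agrees with −kT ln(Boltzmann) to 0.145 kT RMSD over all
bins below 4 kT — the residual is mostly finite-lag shallowing of the
barrier top.

The same pipeline runs from the command line:

```sh
stringswarm demo   --config src/stringswarm/examples/double_well.yaml
stringswarm budget --table my_budget.csv        # appends total µs per system
stringswarm importance --method kl --ensemble frames.csv
```

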