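# 1D quartic double well: the bundled demo system.
potential:
  name: double_well_1d
  params:
    barrier: 3.0
    tilt: 0.0
engine:
  timestep: 0.001
  diffusion_coefficient: 1.0
  kT: 1.0
cv:
  bounds: [[-1.6, 1.6]]
  importance: [1.0]
string:
  n_points: 24
  swarm_min: 16
  swarm_max: 32
  swarm_len: 20
  restrained_len: 30
  max_iterations: 305
  averaging_window: 60
  base_force_constant: 3366.0
string_iterations: 80
grid:
  mins: [-1.5]
  maxs: [1.5]
  n_bins: [30]
basins:
  - name: left
    lo: [-1.5]
    hi: [-0.2]
  - name: right
    lo: [0.2]
    hi: [1.5]
state_sampler:
  iterations: 8
  total: 24
  traj_len: 150
fes:
  production_rounds: 120
  n_posterior_samples: 200
seed: 2024
output_dir: demo_double_well
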