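# Müller–Brown surface scaled so barriers are a few kT.
potential:
  name: muller_brown
  params:
    scale: 0.05
engine:
  timestep: 0.0005
  diffusion_coefficient: 1.0
  kT: 1.0
cv:
  bounds: [[-1.7, 1.3], [-0.5, 2.1]]
  importance: [1.0, 1.0]
string:
  n_points: 25
  swarm_min: 16
  swarm_max: 32
  swarm_len: 20
  restrained_len: 30
  max_iterations: 305
  averaging_window: 60
  base_force_constant: 3366.0
string_iterations: 220
grid:
  mins: [-1.7, -0.5]
  maxs: [1.3, 2.1]
  n_bins: [24, 24]
basins:
  - name: deep
    lo: [-1.0, 1.0]
    hi: [-0.2, 2.0]
  - name: shallow
    lo: [0.2, -0.3]
    hi: [1.1, 0.6]
state_sampler:
  iterations: 8
  total: 24
  traj_len: 150
fes:
  production_rounds: 80
  n_posterior_samples: 200
seed: 7
output_dir: demo_muller_brown
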