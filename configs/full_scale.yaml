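# Full-scale habitat-engineering scenario: 10 x 5 m water column,
# 20 000 fluid particles, 0.5 m/s upper-boundary current, 0.25 m coral
# seed.  Expect hours of runtime on one CPU at this scale; use
# configs/reduced_scale.yaml for test-budget runs.
domain:
  width: 10.0
  height: 5.0
  dx: 0.05
  seed_radius: 0.25
  lid_speed: 0.5
fluid:
  rho0: 1000.0
  mu: 0.001          # sea water, Pa s
  cs: 10.0           # >= 10x any flow speed
  gamma: 7
  epsilon: 0.01
kernel:
  h_over_dx: 1.3
goldilocks:
  v_opt_min: 0.03
  v_opt_max: 0.06
  proximity_dx: 1.5
  settle_steps: 300
  avg_window: 50
  death_interval: 5
  n_growth_steps: 60
step:
  cfl_coeff: 0.25
  n_euler: 50
output:
  directory: out/full_scale
  snapshot_steps: [0, 30, 60]
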