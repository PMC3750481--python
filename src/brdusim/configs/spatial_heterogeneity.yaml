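name: spatial_heterogeneity
population:
  n_init: 1000.0
  division_rate: 0.1
  death_rate: 0.1
  truncation_order: 20
phases:
- duration_d: 10.0
  efficacy:
    variant: mixture
    weights:
    - 0.3333333333333333
    - 0.6666666666666666
    means:
    - 0.5
    - 1.0
    sigma: 0.05
output:
  eval_times_d:
  - 2.0
  - 4.0
  - 6.0
  - 8.0
  - 10.0
  grid:
    x_min: -0.5
    x_max: 1.5
    n_points: 2001
  sample_size: 10000
  thresholds:
  - 0.1
  seed: 1
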