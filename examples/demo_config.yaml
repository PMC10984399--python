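# End-to-end demo: simulate a full experiment shaped like the packaged
# design, score it, build effect sizes, fit the meta-regression, and write
# diagnostic figures.  All randomness flows from simulate.seed (overridable
# with `evofit run --seed`).
design: packaged

simulate:
  seed: 42
  truth:
    sigma2_pop: 0.0
    sigma2_block: 0.0066
    sigma2_obs: 0.0208

propagation:
  assumed_proportion_variance: 0.0005
  rho_within_block: 0.8
  use_observed_binomial: false

effects:
  df: 6.0
  variance_mode: standard

fit: {}

report:
  plots: true

out_dir: demo_out
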