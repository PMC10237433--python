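# Full-pipeline configuration: synthetic two-group study, all three models.
# Run:  gngbias run-all --config examples/config.yaml --out results/
seed: 1
out: gngbias_out
models: [M1, M2, M3]
exclude_threshold: 0.1
mcmc:
  chains: 4
  warmup: 1000
  keep: 1000
  target_accept: 0.8
priors:
  mu_sd_bounded: 1.0
  mu_sd_unbounded: 10.0
  sigma_sd: 1.0
synthetic:
  n_subjects_a: 17
  n_subjects_b: 14
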