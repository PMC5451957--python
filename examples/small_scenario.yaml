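# Small end-to-end demonstration scenario: 120 subjects, 3 planted use
# patterns, full pipeline.  MCMC lengths are kept short so the whole run
# finishes in a couple of minutes; raise bpr.n_sweeps (the study-scale
# analysis used 20,000 burn-in / 200,000 sweeps) for production runs.
seed: 20260926
outdir: runs/small_scenario
stages: [simulate, build-exposure, fit-bpr, characterize, fit-bkmr, spatial, report]

scenario:
  n_subjects: 120
  n_true_clusters: 3
  within_class_correlation: 0.8
  noise_sd: 10.0
  outcome_effects: [0.0, -6.9, -6.4]
  grid_shape: [12, 8]

exposure:
  radius_m: 1000.0
  min_days: 75
  min_trimesters: 2

bpr:
  n_burnin: 500
  n_sweeps: 5000
  truncation_level: 50
  variable_selection: continuous
  outcome_included: true
  sensitivity: true        # refit without the outcome and cross-tabulate

bkmr:
  n_iter: 1000
  n_burnin: 200
  group_prior_prob: 0.5

spatial:
  k: 8
  n_perm: 999
  kde_bandwidth_m: 1500.0
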