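# Desk-scale smoke configuration: 8 participants, decoding decimated to
# 5 ms steps with 5 iterations, 500 permutations.  Same structure as the
# full preset; completes in about a minute on one CPU.
seed: 1
design:
  presentations_per_melody: 20
  omission_rate: 0.5
simulation:
  n_participants: 8
  artifact_fraction: 0.02
  dtype: float32
preprocess: {}
erp:
  search: [50, 110]
  half_width: 10
decode:
  enabled: true
  n_folds: 3
  n_iterations: 5
  decimate: 5
  decode_range: [-200, 300]
stats:
  n_permutations: 500
  cluster_alpha: 0.05
  tail: two
  bf_prior_r: 0.707
  power: {dz: 0.66, alpha: 0.05, power: 0.80}
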