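# Full-scale configuration: 25 participants, full-rate decoding
# (every 1 ms sample, 20 iterations), 10,000 permutations.
seed: 1
design:
  presentations_per_melody: 20
  omission_rate: 0.5
simulation:
  n_participants: 25
  artifact_fraction: 0.02
preprocess: {}
erp:
  search: [50, 110]
  half_width: 10
decode:
  enabled: true
  n_folds: 3
  n_iterations: 20
  decimate: 1
  decode_range: [-200, 300]
stats:
  n_permutations: 10000
  cluster_alpha: 0.05
  tail: two
  bf_prior_r: 0.707
  power: {dz: 0.66, alpha: 0.05, power: 0.80}
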