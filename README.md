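# ospipe

Simulation and analysis pipeline for omitted-stimulus EEG potentials.
`ospipe` builds the trial schedule of a melody-omission experiment,
generates synthetic 34-channel EEG epochs with full ground-truth
bookkeeping, preprocesses them (zero-phase FIR band-pass, amplitude-based
artifact rejection, baseline correction, decoding inclusion gate), measures
the frontocentral omission component from a data-derived peak window,
decodes omitted-note identity per time point with One-vs-Rest linear-margin
classifiers under repeated 3-fold cross-validation, and runs the inference
layer: paired/one-sample t-tests with dz, JZS Bayes factors (Cauchy prior,
r = 0.707), time-axis cluster-based permutation tests, and noncentral-t
power analysis.

## Package layout

| module | contents |
| --- | --- |
| `ospipe.design` | melody specs, balanced omission schedule, per-cell counts |
| `ospipe.simulate` | epoch generator (component + note patterns + 1/f noise + artifacts), ground truth |
| `ospipe.preprocess` | FIR design/filtering, rejection, baseline, inclusion gate |
| `ospipe.erp` | averaging, ROI mean, peak-window rule, window amplitude |
| `ospipe.decode` | fold partitioning, batched OvR linear SVM, accuracy time courses |
| `ospipe.stats` | t/dz, JZS Bayes factor, cluster permutation, power analysis |
| `ospipe.pipeline` / `ospipe.cli` | config validation, orchestration, CLI |

## Command line

Runs are driven by a YAML config (see the packaged presets
`src/ospipe/presets/paper_faithful.yaml` and `paper_faithful_small.yaml`):

```bash
ospipe validate config.yaml                 # dry-run config check
ospipe all config.yaml -o runs/demo        # full chain, all tables + report

# or stage by stage (each consumes the previous stage's files):
ospipe simulate  config.yaml -o runs/demo
ospipe preprocess config.yaml -o runs/demo
ospipe erp       config.yaml -o runs/demo
ospipe decode    config.yaml -o runs/demo
ospipe stats     config.yaml -o runs/demo
```

Outputs: `schedule.csv`, `rejection_log.csv`, `amplitudes.csv`,
`grand_average_<condition>.csv`, `window.json`, `accuracy.csv`,
`stat_report.json` / `.txt`. Every table carries a provenance header
(package version, config hash, master seed); a run directory refuses
configs whose hash differs from the one it was created with. Exit codes:
0 success, 2 config error, 3 stage failure.

## Reproducibility

All randomness derives from explicit seeds: the master seed spawns
per-stage streams (design shuffling, cohort simulation, fold partitioning,
permutation null), and per-participant simulation seeds are spawned from
the cohort seed, so any run is bitwise reproducible from its config file.
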