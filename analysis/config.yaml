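# Desk-scale analysis configuration: a 10-subject cohort (2 reserved for
# hyperparameter tuning), 288 trials per subject before rejection, Cz
# features on a 128 Hz grid over the full 2300 ms epoch (294 features).
# Permutation nulls use 40 shuffles and a single CV repeat so the whole
# chain runs in minutes on one CPU; scale these up for a full-size run
# (22 subjects, 15 repetitions, 256 Hz/588 features, 200 shuffles).
n_subjects: 10
n_tuning: 2
design:
  exemplars_per_cell: 8
  repetitions: 6
  catch_rate: 0.07
  sampling_rate: 128.0
  n_samples: 294
profile: CI
effect: {}
noise: {}
rejection:
  mean_rejected: 20.0
  sd_rejected: 16.0
  min_per_stimulus: 3
cv:
  k: 5
  repeats: 3
grid_n_trees: [50, 100]
grid_max_features: [sqrt]
n_perm: 40
perm_repeats: 1
alpha: 0.05
channel: Cz
exclude_catch: true
seed: 20240408
out_dir: results/pipeline
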