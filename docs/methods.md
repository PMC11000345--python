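# Methods

## Scientific setting

Cochlear implants (CIs) transmit a spectrally degraded signal, and many CI
users have difficulty perceiving auditory emotion. One way to probe their
*residual* emotion processing is to decode, from single-trial EEG epochs, the
emotion category (happy / sad / neutral) of the vocal or musical stimulus the
listener heard: above-chance decoding implies that emotion-specific acoustic
cues survive the implant and are encoded neurally, even when conventional
ERP averaging shows no group difference.

`erpdecode` implements that analysis chain as a reusable, fully seeded
pipeline — single-electrode time-point features, random-forest
classification under repeated stratified cross-validation, and a
within-subject label-permutation significance procedure with a group-average
empirical null — together with a synthetic ERP cohort generator so that
every stage can be exercised, calibrated, and stress-tested end-to-end
without access to clinical recordings.

## Synthetic cohort model

**Design.** The default `StudyDesign` mirrors the emulated experiment:
48 distinct stimuli (2 modalities x 3 emotions x 8 exemplars), each repeated
15 times, for 720 trials presented in randomised blocks of 48 (each block
contains every stimulus exactly once). 7% of trials (floor(0.07 x 720) = 50)
are flagged as attention-check ("click") trials. Epochs are single-channel
(Cz) voltage series on the grid t_k = k / f_s, k = 1..588 at f_s = 256 Hz,
spanning ~3.9-2296.9 ms after stimulus onset. The click itself is only
flagged, not added to the waveform: it is a stimulus event whose evoked
response we do not model, and catch trials are excluded before decoding by
default (both paths are supported).

**Waveforms.** Evoked deflections are Gaussian bumps — a closed-form,
smooth choice with exact peak values:

    w(t) = sum_c A_c * attenuation * exp(-(t - mu_c)^2 / (2 sigma_c^2)) + late(t)

with default components N100 (-5 uV, 100 ms, SD 20 ms), P200 (+6 uV, 200 ms,
SD 30 ms) and a late positivity (+2 uV, 725 ms, SD 80 ms). Emotion enters in
two places, both scaled by a global `effect_scale`:

* sad trials delay the N100 and P200 peaks by `latency_shift_sad`
  (default 20 ms);
* emotional (happy and sad) trials carry a uniform `late_offset`
  (default +1 uV vs. 0 for neutral) inside the 600-850 ms late window,
  the portion of the evoked response where emotional/neutral
  differentiation is reported in normal-hearing listeners.

`effect_scale = 0` removes every label-dependent term, so the emotion label
is exactly independent of the signal — the construction used for all type-I
error studies. Group profiles modulate the whole response: the CI profile
attenuates amplitudes (x0.8) and prolongs latencies (x1.1) relative to the
normal-hearing (NH) profile, reflecting the attenuated and prolonged early
responses reported for implant users. The defaults are configuration, not
contract.

**Noise.** Per-trial noise is white Gaussian (SD 2 uV) plus 1/f-shaped
"pink" noise (SD 2 uV), the standard minimal model of background EEG;
between-subject variability adds Gaussian offsets to each component's
amplitude (SD 0.5 uV) and latency (SD 5 ms). These magnitudes were chosen
once as EEG-plausible values that leave single-trial decoding modestly above
chance at `effect_scale = 1` — single-trial ERPs have strongly negative SNR,
and published decoding effects in this paradigm are of the order of 5-10
percentage points, not near-perfect classification.

**Trial rejection.** Artifact rejection is emulated by drawing a rejection
count from a normal distribution (mean 40, SD 32) truncated to
[0, max feasible] and rejecting that many trials uniformly at random,
subject to every stimulus retaining at least `min_per_stimulus = 5` of its
15 repetitions (a shuffled single pass that skips trials whose stimulus has
reached the floor; the truncation bound makes the target always reachable).
If the requested mean exceeds what the floor allows, generation fails with
an explicit error.

**Seeding.** A master seed fixes everything. Subject i of a cohort uses seed
`master + i`, so cohorts are reproducible subject-by-subject and extending a
cohort never changes existing subjects. Permutation r of a significance run
is seeded from the pair `(seed, r)`. Identical seeds give bit-identical
epochs, fold assignments, forests, and reports.

## Features

Decoding uses the raw microvolt level at each retained (non-catch) trial and
each time point of one electrode — 588 features for the default design. No
baseline correction, detrending, filtering or normalisation is applied. The
time grid is a documented convention (sample k at k / f_s): the emulated
recording was sampled at 1024 Hz and yields 588 features over 2300 ms, which
implies 4x decimation upstream; the reader accepts native 256 Hz input or
decimates by stride. When Cz is absent, it is reconstructed as the
unweighted sample-wise mean of the lateral neighbours C1 and C2
(`interpolate_channel`); spherical-spline interpolation is out of scope.
Binary schemes (happy-sad, happy-neutral, sad-neutral) drop trials of the
third emotion and never alter feature values.

## Decoding

The classifier is a random forest: 100 bootstrap-bagged CART trees with
sqrt(n_features) candidate features per split (the grid-search winners),
soft voting across trees. It is implemented as a thin, fully seeded bagging
ensemble over `sklearn.tree.DecisionTreeClassifier`: the ensemble loop is
deliberately minimal so that the tens of thousands of small fits needed by
permutation calibration studies remain cheap on one CPU, and tests
cross-check its accuracy against `sklearn.ensemble.RandomForestClassifier`
on matched data.

Evaluation is stratified 5-fold cross-validation repeated 3 times (4:1
train-test split). Each repeat draws a fresh seeded partition; stratification
is asserted on every generated partition (per-fold class counts within one
trial of n_class/5). The repeat's accuracy is trial-weighted across folds
(total correct / total trials) and the subject's score is the unweighted
mean over repeats — with near-balanced folds the weighting choice is
negligible. Above-chance accuracy is `100 * (accuracy - 1/n_classes)`
percentage points; the theoretical chance level is used rather than the
majority-class rate because classes are balanced by design.

Hyperparameters are chosen by grid search (default grid:
n_trees in {50, 100, 200, 500} x max-features rule in {sqrt, log2, 0.5}) on
reserved tuning subjects — 2 of the 22 by default — who are excluded from
every subsequent analysis; the exclusion is enforced by subject-id
bookkeeping, and the group summary refuses results that contain a tuning
subject. Ties go to the first-listed grid cell.

## Permutation significance

Within each subject, the label vector is shuffled uniformly (features
untouched) and the *identical* CV pipeline re-run, `n_perm = 200` times by
default. The r-th shuffles are averaged across subjects, giving a
group-average empirical null of 200 group-mean accuracies. The significance
boundary is the nearest-rank 95th percentile (the ceil(0.95 n)-th order
statistic; no interpolation rule is assumed), and an observed group-mean
accuracy is declared significant when it strictly exceeds the boundary.
Alongside the flag, an add-one empirical p-value is reported:

    p = (1 + #{r : null_r >= observed}) / (1 + n_perm)

which is never smaller than 1/(n_perm + 1) and remains valid at finite
n_perm. With n_perm = 50 the boundary rule's exact per-test level under
exchangeability is 3/51 ~= 0.059 (slightly above 0.05 by discreteness of the
nearest rank), while the add-one p rule is conservative (2/51 ~= 0.039); the
calibration study checks the boundary rule against the binomial envelope of
the nominal level. Permutation runs may use fewer CV repeats than the
observed analysis for tractability (configurable; the reduction is logged
prominently). One null is built per scheme; no multiple-testing correction
is applied across the four schemes.

## Group report

Per scheme, the report carries the unweighted subject mean and the standard
error (sample SD, n-1 denominator, over subjects divided by sqrt(n); 0 by
convention for a single subject) of above-chance accuracy, every subject's
individual value, the permutation p-value and the significance flag. The
figure shows the three binary bars then the multiclass bar, SEM error bars,
and individual-subject circles.

## Validation studies and problem sizes

Three simulation studies (in `erpdecode.studies`, shared verbatim by the
analysis scripts, the test suite, and `scripts/acceptance.py`) validate the
statistics at sizes chosen for a single CPU:

* **Rejection floor** — 20 default-design subjects under the default
  rejection model; the minimum per-stimulus retained count must be >= 5.
* **Type-I calibration** — 50 zero-effect cohorts of 6 subjects x 60 trials
  x 50 features; 50 permutations, 1 CV repeat, 10-tree forests (type-I
  calibration of a permutation test does not depend on classifier strength,
  so the forest is kept small); the fraction of cohorts whose observed
  group-mean accuracy exceeds the 95th-percentile boundary must stay within
  the 95% binomial envelope of 0.05.
* **Power** — paired-seed cohorts (identical noise, growing signal) at
  effect scales 0, 0.5 and 1 on a 64 Hz grid over the full epoch
  (147 features, so the late window is covered): mean group above-chance
  accuracy must be non-decreasing; and at a deliberately large effect
  (scale 3) all four schemes must clear their permutation boundaries.

## What the synthetic data does and does not show

The generator reproduces the *design* (trial counts, balance, blocks, catch
trials, rejection constraints) and a plausible *signal structure* (component
latency shifts, a late emotional offset, 1/f noise, subject variability).
It does not model implant electrical artifact, ocular or movement artifacts,
non-stationarity across the session, stimulus-duration differences between
vocal (≈1.5 s) and musical (≈1.7 s) bursts, or channel covariance — there is
only one (optionally interpolated) electrode. Passing tests therefore show
that the pipeline is correct and statistically calibrated, and that it can
recover emotion information when present; they do not certify effect sizes
on real clinical EEG, and the simulator's accuracies should not be read as
predictions of patient data.

## Numerical and design choices

* Nearest-rank quantile for the boundary; add-one p-values; strict `>` at
  the boundary (ties count against significance).
* Rejection counts truncated-normal, then constrained by the per-stimulus
  floor.
* Grid-search ties break to the first-listed cell.
* Forest bootstrap is uniform with replacement; a tree that never sees a
  class simply contributes no probability mass to it.
* Degenerate inputs fail loudly: unknown emotions, missing channels, empty
  classes after subsetting, classes smaller than k, ragged null matrices,
  infeasible rejection means, empty nulls.
* Epoch files round-trip bit-exactly (floats written with 17 significant
  digits).
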