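"""Reusable study procedures: the simulation experiments that validate the
pipeline's statistical behaviour.

Each function runs a self-contained simulation study at a size chosen for a
single CPU (the methods note documents the sizes) and returns plain dicts of
numbers, so the analysis scripts, the test suite and the acceptance script
all exercise the identical code path.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _stats

from .decoding import CvConfig, RfConfig, cross_validated_accuracy, run_all_schemes
from .features import SCHEMES, build_feature_matrix
from .significance import PermutationNull, empirical_p, permuted_accuracies
from .synth import (
    EmotionEffectProfile,
    NoiseModel,
    RejectionModel,
    StudyDesign,
    generate_cohort,
)

#: reduced design used by the calibration/power studies: 2 x 3 x 2 x 5 = 60 trials
SMALL_DESIGN = dict(exemplars_per_cell=2, repetitions=5, catch_rate=0.0)


def rejection_floor_study(seed: int = 0, n_subjects: int = 20) -> dict:
    """Minimum per-stimulus retained trial count across a simulated cohort
    under the default rejection model (mean 40 rejected, SD 32, floor 5).

    Returns the minimum over all subjects and stimuli, which the rejection
    model must keep at or above its ``min_per_stimulus`` floor.
    """
    cohort = generate_cohort(n_subjects, StudyDesign(), rejection=RejectionModel(), seed=seed)
    min_retained = np.inf
    total_rejected = []
    for subj in cohort:
        counts = subj.labels.loc[subj.retained, "stim_id"].value_counts()
        counts = counts.reindex(range(subj.labels["stim_id"].nunique()), fill_value=0)
        min_retained = min(min_retained, int(counts.min()))
        total_rejected.append(int((~subj.retained).sum()))
    return {
        "min_retained_per_stimulus": int(min_retained),
        "mean_rejected": float(np.mean(total_rejected)),
        "n_subjects": n_subjects,
    }


def _null_cohort_settings() -> tuple[StudyDesign, EmotionEffectProfile, NoiseModel]:
    design = StudyDesign(n_samples=50, **SMALL_DESIGN)
    effect = EmotionEffectProfile(effect_scale=0.0)
    return design, effect, NoiseModel()


def null_calibration_study(
    seed: int = 0,
    n_cohorts: int = 50,
    n_subjects: int = 6,
    n_perm: int = 50,
    n_trees: int = 10,
    alpha: float = 0.05,
) -> dict:
    """Empirical type-I error of the group permutation boundary on cohorts
    with zero emotion effect.

    Each cohort: ``n_subjects`` subjects x 60 trials x 50 features with
    ``effect_scale = 0`` (labels independent of the signal); the multiclass
    observed group-mean accuracy is compared to the nearest-rank 95th
    percentile of its group-average null (``n_perm`` within-subject
    shuffles, 1 CV repeat). Returns the fraction of cohorts declared
    significant — the false-positive rate, nominally at most ~alpha.
    """
    design, effect, noise = _null_cohort_settings()
    rng = np.random.default_rng(seed)
    cohort_seeds = rng.integers(2**30, size=n_cohorts)
    flags = []
    p_values = []
    for cs in cohort_seeds:
        cs = int(cs)
        cohort = generate_cohort(
            n_subjects, design, effect=effect, noise=noise, rejection=None, seed=cs
        )
        cv = CvConfig(k=5, repeats=1, seed=cs)
        rf = RfConfig(n_trees=n_trees, seed=cs)
        observed = []
        per_subject = []
        for si, subj in enumerate(cohort):
            fm = build_feature_matrix(subj, scheme="multiclass")
            observed.append(cross_validated_accuracy(fm, cv, rf).mean_accuracy)
            per_subject.append(
                permuted_accuracies(fm, cv, rf, n_perm=n_perm, seed=cs + 104729 * (si + 1))
            )
        null = PermutationNull.from_per_subject(per_subject, alpha=alpha, scheme="multiclass")
        obs_mean = float(np.mean(observed))
        flags.append(obs_mean > null.boundary)
        p_values.append(empirical_p(obs_mean, null.group_null))
    n_sig = int(np.sum(flags))
    return {
        "false_positive_rate": n_sig / n_cohorts,
        "n_significant": n_sig,
        "n_cohorts": n_cohorts,
        "alpha": alpha,
        "binomial_upper_fraction": float(_stats.binom.ppf(0.95, n_cohorts, alpha)) / n_cohorts,
        "mean_p": float(np.mean(p_values)),
    }


def power_study(
    seed: int = 0,
    effect_scales: tuple[float, ...] = (0.0, 0.5, 1.0),
    large_scale: float = 3.0,
    n_subjects: int = 5,
    n_perm: int = 50,
    n_trees: int = 25,
    alpha: float = 0.05,
) -> dict:
    """Decoding accuracy versus emotion-effect size, with paired seeds.

    The same cohort seeds are reused at every ``effect_scale``, so the noise
    realisations are identical and only the label-dependent signal grows —
    mean group above-chance accuracy must be non-decreasing over
    ``effect_scales``. Uses a 64 Hz grid over the full 2300 ms epoch
    (147 features) so the 600-850 ms late window is inside the feature span.
    Separately, at ``large_scale`` (an effect big enough to dominate the
    noise; the default unit scale is deliberately modest, like real
    single-trial EEG) a permutation null (``n_perm`` shuffles) is built per
    scheme to check that every scheme reaches significance.
    """
    design = StudyDesign(sampling_rate=64.0, n_samples=147, **SMALL_DESIGN)
    cv = CvConfig(k=5, repeats=1, seed=seed)
    rf = RfConfig(n_trees=n_trees, seed=seed)

    mean_above: dict[float, float] = {}
    for scale in effect_scales:
        effect = EmotionEffectProfile(effect_scale=scale)
        cohort = generate_cohort(
            n_subjects, design, effect=effect, rejection=None, seed=seed
        )
        per_subject = [run_all_schemes(subj, cv, rf) for subj in cohort]
        above = [r.above_chance for rs in per_subject for r in rs]
        mean_above[scale] = float(np.mean(above))

    effect = EmotionEffectProfile(effect_scale=large_scale)
    cohort = generate_cohort(n_subjects, design, effect=effect, rejection=None, seed=seed)
    per_subject = [run_all_schemes(subj, cv, rf) for subj in cohort]
    significant: dict[str, bool] = {}
    p_values: dict[str, float] = {}
    for k, scheme in enumerate(SCHEMES):
        vecs = []
        for si, subj in enumerate(cohort):
            fm = build_feature_matrix(subj, scheme=scheme)
            vecs.append(
                permuted_accuracies(fm, cv, rf, n_perm=n_perm, seed=seed + 104729 * (si + 1) + k)
            )
        null = PermutationNull.from_per_subject(vecs, alpha=alpha, scheme=scheme)
        obs = float(np.mean([rs[k].mean_accuracy for rs in per_subject]))
        assert per_subject[0][k].scheme == scheme
        significant[scheme] = obs > null.boundary
        p_values[scheme] = empirical_p(obs, null.group_null)
    return {
        "mean_above_chance_by_scale": mean_above,
        "monotone": all(
            mean_above[a] <= mean_above[b] + 1e-12
            for a, b in zip(sorted(mean_above), sorted(mean_above)[1:])
        ),
        "large_scale": large_scale,
        "significant_at_large": significant,
        "p_values_at_large": p_values,
        "n_subjects": n_subjects,
    }
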