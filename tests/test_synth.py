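"""Synthetic cohort generator: waveform composition, design closure,
randomisation, rejection constraints, and seed determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from erpdecode import (
    DEFAULT_COMPONENTS,
    EMOTIONS,
    EmotionEffectProfile,
    ErpComponent,
    NoiseModel,
    RejectionModel,
    StudyDesign,
    apply_trial_rejection,
    erp_waveform,
    generate_cohort,
    generate_subject,
)

GRID = np.arange(1, 589) * (1000.0 / 256.0)


class TestErpWaveform:
    def test_empty_components_give_zero_series(self):
        no_offset = EmotionEffectProfile(late_offset={})
        for emotion in EMOTIONS:
            assert np.all(erp_waveform([], no_offset, emotion, GRID) == 0.0)
        # neutral carries no late offset under the default profile either
        assert np.all(erp_waveform([], EmotionEffectProfile(), "neutral", GRID) == 0.0)

    def test_zero_effect_scale_makes_emotions_identical(self):
        effect = EmotionEffectProfile(effect_scale=0.0)
        waves = [erp_waveform(DEFAULT_COMPONENTS, effect, e, GRID) for e in EMOTIONS]
        assert np.array_equal(waves[0], waves[1])
        assert np.array_equal(waves[0], waves[2])

    def test_single_component_peak_value(self):
        comp = [ErpComponent("N100", -5.0, 100.0, 20.0)]
        effect = EmotionEffectProfile(attenuation=1.0, effect_scale=0.0)
        grid = np.array([50.0, 100.0, 150.0])
        w = erp_waveform(comp, effect, "neutral", grid)
        assert w[1] == pytest.approx(-5.0)

    def test_sad_latency_shift_moves_n100_peak(self):
        comp = [ErpComponent("N100", -5.0, 100.0, 20.0)]
        effect = EmotionEffectProfile(latency_shift_sad=20.0, effect_scale=1.0)
        grid = np.arange(0.0, 400.0, 1.0)
        sad = erp_waveform(comp, effect, "sad", grid)
        happy = erp_waveform(comp, effect, "happy", grid)
        assert grid[np.argmin(sad)] == pytest.approx(120.0)
        assert grid[np.argmin(happy)] == pytest.approx(100.0)

    def test_late_window_offset_applies_only_inside_window(self):
        effect = EmotionEffectProfile(late_window=(600.0, 850.0))
        happy = erp_waveform([], effect, "happy", GRID)
        neutral = erp_waveform([], effect, "neutral", GRID)
        inside = (GRID >= 600) & (GRID <= 850)
        assert np.all(happy[inside] - neutral[inside] == pytest.approx(1.0))
        assert np.all(happy[~inside] == neutral[~inside])

    def test_unknown_emotion_rejected(self):
        with pytest.raises(ValueError, match="unknown emotion"):
            erp_waveform(DEFAULT_COMPONENTS, EmotionEffectProfile(), "angry", GRID)

    @given(scale=st.floats(0.0, 5.0), amp=st.floats(-10.0, 10.0))
    @settings(deadline=None, max_examples=25)
    def test_zero_scale_invariant_for_arbitrary_components(self, scale, amp):
        comp = [ErpComponent("N100", amp, 120.0, 25.0)]
        e0 = EmotionEffectProfile(effect_scale=0.0, latency_shift_sad=scale * 10)
        waves = {e: erp_waveform(comp, e0, e, GRID) for e in EMOTIONS}
        assert np.array_equal(waves["happy"], waves["sad"])
        assert np.array_equal(waves["happy"], waves["neutral"])

    def test_between_class_distance_monotone_in_effect_scale(self):
        dists = []
        for scale in (0.0, 0.5, 1.0, 2.0):
            eff = EmotionEffectProfile(effect_scale=scale)
            sad = erp_waveform(DEFAULT_COMPONENTS, eff, "sad", GRID)
            neu = erp_waveform(DEFAULT_COMPONENTS, eff, "neutral", GRID)
            dists.append(np.linalg.norm(sad - neu))
        assert all(a <= b + 1e-12 for a, b in zip(dists, dists[1:]))


class TestStudyDesign:
    def test_default_design_closure(self):
        d = StudyDesign()
        assert d.n_stimuli == 48
        assert d.n_trials == 720
        assert d.n_samples == 588

    def test_time_grid_convention(self):
        t = StudyDesign().time_grid()
        assert t[0] == pytest.approx(1000.0 / 256.0)
        assert t[-1] == pytest.approx(588 * 1000.0 / 256.0)
        assert t[-1] <= 2300.0

    def test_grid_must_fit_epoch(self):
        with pytest.raises(ValueError, match="epoch_ms"):
            StudyDesign(n_samples=1000, epoch_ms=2300.0)


class TestGenerateSubject:
    def test_default_trial_and_stimulus_counts(self):
        s = generate_subject(StudyDesign(), rejection=None, seed=0)
        assert s.n_trials == 720
        assert s.labels["stim_id"].nunique() == 48
        assert (s.labels["emotion"].value_counts() == 240).all()

    def test_catch_trial_count_is_floor_of_rate(self):
        s = generate_subject(StudyDesign(), rejection=None, seed=0)
        assert int(s.labels["catch"].sum()) == 50  # floor(0.07 * 720)

    def test_each_block_contains_every_stimulus_once(self, small_design):
        s = generate_subject(small_design, rejection=None, seed=5)
        ns = small_design.n_stimuli
        for b in range(small_design.repetitions):
            block = s.labels["stim_id"].iloc[b * ns:(b + 1) * ns]
            assert sorted(block) == list(range(ns))

    def test_seed_determinism(self, small_design):
        a = generate_subject(small_design, seed=42, rejection=None)
        b = generate_subject(small_design, seed=42, rejection=None)
        assert np.array_equal(a.data, b.data)
        assert a.labels.equals(b.labels)
        assert np.array_equal(a.retained, b.retained)

    def test_noiseless_null_trials_identical(self, small_design):
        s = generate_subject(
            small_design,
            effect=EmotionEffectProfile(effect_scale=0.0),
            noise=NoiseModel(0.0, 0.0, 0.0, 0.0),
            rejection=None,
            seed=1,
        )
        cz = s.channel_data("Cz")
        assert np.all(cz == cz[0])


class TestTrialRejection:
    def test_zero_rejection_leaves_mask_unchanged(self, small_subject):
        out = apply_trial_rejection(small_subject, RejectionModel(0.0, 0.0, 5), seed=0)
        assert np.array_equal(out.retained, small_subject.retained)

    def test_fixed_count_rejects_exactly(self):
        s = generate_subject(StudyDesign(), rejection=None, seed=2)
        out = apply_trial_rejection(s, RejectionModel(40.0, 0.0, 5), seed=0)
        assert int(out.retained.sum()) == 680  # 720 - 40

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_per_stimulus_floor_always_respected(self, seed):
        s = generate_subject(StudyDesign(), rejection=None, seed=seed)
        hard = RejectionModel(mean_rejected=300.0, sd_rejected=100.0, min_per_stimulus=5)
        out = apply_trial_rejection(s, hard, seed=seed)
        counts = out.labels.loc[out.retained, "stim_id"].value_counts()
        assert counts.min() >= 5

    def test_infeasible_rejection_raises(self, small_subject):
        # 60 trials, floor 5 of 5 repetitions -> nothing removable
        with pytest.raises(ValueError, match="infeasible"):
            apply_trial_rejection(small_subject, RejectionModel(10.0, 0.0, 5), seed=0)

    def test_labels_and_data_untouched(self, small_subject):
        out = apply_trial_rejection(small_subject, RejectionModel(5.0, 2.0, 2), seed=9)
        assert out.labels.equals(small_subject.labels)
        assert np.array_equal(out.data, small_subject.data)


class TestGenerateCohort:
    def test_distinct_subject_ids(self, small_design):
        cohort = generate_cohort(4, small_design, rejection=None, seed=0)
        ids = [s.subject_id for s in cohort]
        assert len(set(ids)) == 4

    def test_same_master_seed_identical_cohorts(self, small_design):
        a = generate_cohort(3, small_design, rejection=None, seed=5)
        b = generate_cohort(3, small_design, rejection=None, seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x.data, y.data)

    def test_cohort_extension_preserves_earlier_subjects(self, small_design):
        a = generate_cohort(2, small_design, rejection=None, seed=5)
        b = generate_cohort(4, small_design, rejection=None, seed=5)
        assert np.array_equal(a[1].data, b[1].data)

    def test_zero_subject_variability_shares_expected_waveforms(self, small_design):
        noise = NoiseModel(0.0, 0.0, 0.0, 0.0)
        cohort = generate_cohort(3, small_design, noise=noise, rejection=None, seed=0)
        # noiseless and no subject effects -> per-emotion waveforms equal across subjects
        for e in EMOTIONS:
            rows = [
                s.channel_data("Cz")[s.labels["emotion"].to_numpy() == e][0]
                for s in cohort
            ]
            assert np.array_equal(rows[0], rows[1])
            assert np.array_equal(rows[0], rows[2])

    def test_requires_at_least_one_subject(self, small_design):
        with pytest.raises(ValueError):
            generate_cohort(0, small_design)
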