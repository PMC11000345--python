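"""Cross-validated random-forest decoding: determinism, chance calibration,
stratification, scheme coverage, and the hyperparameter search."""

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from erpdecode import (
    CvConfig,
    FeatureMatrix,
    RfConfig,
    above_chance,
    cross_validated_accuracy,
    grid_search,
    run_all_schemes,
)
from erpdecode._forest import SeededRandomForest


def _fm(values, labels, classes, scheme="happy-sad"):
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(
        values=values,
        feature_times=np.arange(1, values.shape[1] + 1, dtype=float),
        labels=np.asarray(labels),
        scheme=scheme,
        class_names=tuple(classes),
        trial_ids=np.arange(len(labels)),
        subject_id="sub-t",
    )


class TestCrossValidatedAccuracy:
    def test_separable_constant_classes_score_perfectly(self):
        X = np.vstack([np.full((20, 4), 1.0), np.full((20, 4), -1.0)])
        y = np.array(["happy"] * 20 + ["sad"] * 20)
        res = cross_validated_accuracy(_fm(X, y, ("happy", "sad")), CvConfig(), RfConfig(n_trees=10))
        assert res.mean_accuracy == 1.0
        assert res.above_chance == pytest.approx(50.0)

    def test_null_features_score_at_chance_over_seeds(self, rng):
        # 3 classes, pure-noise features: mean accuracy over seeds ~ 1/3
        accs = []
        for seed in range(8):
            X = rng.normal(size=(60, 10))
            y = np.repeat(["happy", "sad", "neutral"], 20)
            res = cross_validated_accuracy(
                _fm(X, y, ("happy", "sad", "neutral"), "multiclass"),
                CvConfig(repeats=1, seed=seed),
                RfConfig(n_trees=15, seed=seed),
            )
            accs.append(res.mean_accuracy)
        assert np.mean(accs) == pytest.approx(1.0 / 3.0, abs=0.06)

    def test_deterministic_given_seeds(self, small_subject):
        from erpdecode import build_feature_matrix

        fm = build_feature_matrix(small_subject)
        cv, rf = CvConfig(repeats=2, seed=5), RfConfig(n_trees=10, seed=5)
        a = cross_validated_accuracy(fm, cv, rf)
        b = cross_validated_accuracy(fm, cv, rf)
        assert a.per_repeat_accuracy == b.per_repeat_accuracy

    def test_class_smaller_than_k_raises(self):
        X = np.random.default_rng(0).normal(size=(24, 3))
        y = np.array(["happy"] * 21 + ["sad"] * 3)
        with pytest.raises(ValueError, match="sad"):
            cross_validated_accuracy(_fm(X, y, ("happy", "sad")), CvConfig(k=5))

    def test_repeat_count_respected(self, small_subject):
        from erpdecode import build_feature_matrix

        fm = build_feature_matrix(small_subject)
        res = cross_validated_accuracy(fm, CvConfig(repeats=2), RfConfig(n_trees=5))
        assert len(res.per_repeat_accuracy) == 2
        assert res.mean_accuracy == pytest.approx(np.mean(res.per_repeat_accuracy))


class TestAboveChance:
    @pytest.mark.parametrize(
        "acc,k,expected",
        [(1.0 / 3.0, 3, 0.0), (0.578, 2, 7.8), (1.0, 2, 50.0)],
    )
    def test_examples(self, acc, k, expected):
        assert above_chance(acc, k) == pytest.approx(expected)

    def test_requires_two_classes(self):
        with pytest.raises(ValueError):
            above_chance(0.5, 1)


class TestRunAllSchemes:
    def test_four_schemes_with_correct_chance(self, small_subject):
        results = run_all_schemes(small_subject, CvConfig(repeats=1), RfConfig(n_trees=5))
        assert [r.scheme for r in results] == [
            "multiclass", "happy-sad", "happy-neutral", "sad-neutral",
        ]
        assert results[0].chance == pytest.approx(1 / 3)
        assert all(r.chance == pytest.approx(1 / 2) for r in results[1:])

    def test_same_seed_identical(self, small_subject):
        cv, rf = CvConfig(repeats=1, seed=2), RfConfig(n_trees=5, seed=2)
        a = run_all_schemes(small_subject, cv, rf)
        b = run_all_schemes(small_subject, cv, rf)
        assert [r.mean_accuracy for r in a] == [r.mean_accuracy for r in b]


class TestGridSearch:
    def test_single_cell_grid_returns_it(self, small_subject):
        rf = RfConfig(n_trees=5, seed=0)
        out = grid_search([small_subject], [rf], CvConfig(repeats=1))
        assert out.best == rf
        assert out.tuning_subject_ids == (small_subject.subject_id,)

    def test_tie_break_prefers_first_cell(self, small_subject):
        rf = RfConfig(n_trees=5, seed=0)
        out = grid_search([small_subject], [rf, rf], CvConfig(repeats=1))
        assert int(out.scores["mean_accuracy"].idxmax()) == 0
        assert out.best is not None

    def test_empty_grid_raises(self, small_subject):
        with pytest.raises(ValueError):
            grid_search([small_subject], [], CvConfig())


class TestSeededForest:
    def test_deterministic(self, rng):
        X = rng.normal(size=(40, 6))
        y = rng.integers(0, 2, 40)
        a = SeededRandomForest(20, "sqrt", seed=3).fit(X, y).predict(X)
        b = SeededRandomForest(20, "sqrt", seed=3).fit(X, y).predict(X)
        assert np.array_equal(a, b)

    def test_agrees_with_sklearn_forest(self, rng):
        # independent cross-check: both forests should reach similar accuracy
        # on moderately separated Gaussian classes
        n = 300
        X = np.vstack([rng.normal(0, 1, (n, 8)), rng.normal(1.2, 1, (n, 8))])
        y = np.repeat([0, 1], n)
        Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=0.4, random_state=0, stratify=y)
        ours = SeededRandomForest(100, "sqrt", seed=0).fit(Xtr, ytr)
        theirs = RandomForestClassifier(100, max_features="sqrt", random_state=0).fit(Xtr, ytr)
        acc_ours = np.mean(ours.predict(Xte) == yte)
        acc_theirs = np.mean(theirs.predict(Xte) == yte)
        assert acc_ours == pytest.approx(acc_theirs, abs=0.05)

    @pytest.mark.parametrize("rule", ["sqrt", "log2", 0.5])
    def test_max_features_rules_accepted(self, rule, rng):
        X = rng.normal(size=(30, 9))
        y = rng.integers(0, 3, 30)
        preds = SeededRandomForest(5, rule, seed=1).fit(X, y).predict(X)
        assert preds.shape == (30,)
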