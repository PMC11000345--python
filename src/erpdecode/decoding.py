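"""Per-subject emotion decoding under repeated stratified k-fold CV.

A random forest (100 trees, sqrt feature rule by default) is evaluated with
stratified 5-fold cross-validation repeated 3 times; each repeat draws a
fresh seeded partition, accuracy is the trial-weighted mean over the held-out
folds, and the subject's score is the unweighted mean over repeats. The
multiclass problem (happy / sad / neutral) and the three binary pairings are
run side by side; hyperparameters come from a grid search on reserved tuning
subjects that are excluded from all subsequent analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._forest import SeededRandomForest
from .features import SCHEMES, FeatureMatrix, build_feature_matrix
from .synth import EpochSet


@dataclass(frozen=True)
class RfConfig:
    """Random-forest hyperparameters (the grid-search winners by default)."""

    n_trees: int = 100
    max_features_rule: str | float = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if isinstance(self.max_features_rule, float) and not 0 < self.max_features_rule <= 1:
            raise ValueError("fractional max_features_rule must be in (0, 1]")


@dataclass(frozen=True)
class CvConfig:
    """Repeated stratified k-fold settings (5 folds x 3 repeats, 4:1 split)."""

    k: int = 5
    repeats: int = 3
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not self.stratified:
            raise ValueError("only stratified CV is supported")


@dataclass
class DecodingResult:
    subject_id: str
    scheme: str
    per_repeat_accuracy: list[float]
    mean_accuracy: float
    chance: float

    @property
    def above_chance(self) -> float:
        """Percentage points above the theoretical chance level."""
        return above_chance(self.mean_accuracy, round(1.0 / self.chance))


def above_chance(mean_accuracy: float, n_classes: int) -> float:
    """Accuracy minus chance (1/n_classes), in percentage points."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    return 100.0 * (mean_accuracy - 1.0 / n_classes)


def _check_stratification(y: np.ndarray, folds: list[np.ndarray], n_classes: int) -> None:
    """Every fold's class counts stay within one trial of proportionality."""
    k = len(folds)
    for test_idx in folds:
        for c in range(n_classes):
            expected = np.sum(y == c) / k
            got = np.sum(y[test_idx] == c)
            assert abs(got - expected) < 1.0 + 1e-9, (
                f"fold class count {got} deviates from proportional {expected:.2f}"
            )


def cross_validated_accuracy(
    features: FeatureMatrix, cv: CvConfig = CvConfig(), rf: RfConfig = RfConfig()
) -> DecodingResult:
    """Repeated stratified k-fold accuracy of the forest on one subject.

    Per repeat: a fresh seeded stratified partition; per fold: a forest
    trained on the k-1 training folds, scored on the held-out fold. The
    repeat accuracy is total-correct / total-trials (trial-weighted over
    folds); ``mean_accuracy`` is the unweighted mean over repeats.
    """
    classes = features.class_names
    # map labels -> stable integer codes in class_names order
    code = {c: i for i, c in enumerate(classes)}
    y = np.array([code[l] for l in features.labels])
    X = features.values
    for c, i in code.items():
        if np.sum(y == i) < cv.k:
            raise ValueError(
                f"class {c!r} has {int(np.sum(y == i))} trials; needs >= k={cv.k}"
            )
    master = np.random.default_rng([cv.seed, rf.seed])
    split_seeds = master.integers(2**31, size=cv.repeats)
    tree_seeds = master.integers(2**31, size=(cv.repeats, cv.k))
    per_repeat = []
    for r in range(cv.repeats):
        skf = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=int(split_seeds[r]))
        folds = [test for _, test in skf.split(X, y)]
        _check_stratification(y, folds, len(classes))
        correct = 0
        for f, test_idx in enumerate(folds):
            train_mask = np.ones(y.size, dtype=bool)
            train_mask[test_idx] = False
            forest = SeededRandomForest(
                rf.n_trees, rf.max_features_rule, seed=int(tree_seeds[r, f])
            )
            forest.fit(X[train_mask], y[train_mask], n_classes=len(classes))
            correct += int(np.sum(forest.predict(X[test_idx]) == y[test_idx]))
        per_repeat.append(correct / y.size)
    return DecodingResult(
        subject_id=features.subject_id,
        scheme=features.scheme,
        per_repeat_accuracy=per_repeat,
        mean_accuracy=float(np.mean(per_repeat)),
        chance=1.0 / len(classes),
    )


def run_all_schemes(
    epochs: EpochSet,
    cv: CvConfig = CvConfig(),
    rf: RfConfig = RfConfig(),
    channel: str = "Cz",
    window: tuple[float, float] | None = None,
    exclude_catch: bool = True,
) -> list[DecodingResult]:
    """Decode one subject under every scheme: multiclass plus the three
    binary pairings, in the fixed order of :data:`SCHEMES`."""
    results = []
    for scheme in SCHEMES:
        fm = build_feature_matrix(
            epochs, channel=channel, window=window, scheme=scheme, exclude_catch=exclude_catch
        )
        results.append(cross_validated_accuracy(fm, cv, rf))
    return results


@dataclass
class GridSearchOutcome:
    """Winner of the hyperparameter search plus the bookkeeping needed to
    keep tuning subjects out of the analysis set."""

    best: RfConfig
    tuning_subject_ids: tuple[str, ...]
    scores: pd.DataFrame = field(repr=False)  # one row per grid cell


def default_grid(seed: int = 0) -> list[RfConfig]:
    return [
        RfConfig(n_trees=t, max_features_rule=m, seed=seed)
        for t in (50, 100, 200, 500)
        for m in ("sqrt", "log2", 0.5)
    ]


def grid_search(
    tuning_subjects: list[EpochSet],
    grid: list[RfConfig],
    cv: CvConfig = CvConfig(),
    channel: str = "Cz",
    window: tuple[float, float] | None = None,
    exclude_catch: bool = True,
) -> GridSearchOutcome:
    """Pick the grid cell maximising mean accuracy over the tuning subjects
    and all four schemes; ties go to the first-listed cell."""
    if not tuning_subjects:
        raise ValueError("at least one tuning subject required")
    if not grid:
        raise ValueError("grid must be non-empty")
    rows = []
    for gi, rf in enumerate(grid):
        accs = [
            res.mean_accuracy
            for subj in tuning_subjects
            for res in run_all_schemes(
                subj, cv, rf, channel=channel, window=window, exclude_catch=exclude_catch
            )
        ]
        rows.append(
            {
                "grid_index": gi,
                "n_trees": rf.n_trees,
                "max_features_rule": rf.max_features_rule,
                "mean_accuracy": float(np.mean(accs)),
            }
        )
    scores = pd.DataFrame(rows)
    best_idx = int(scores["mean_accuracy"].idxmax())  # idxmax -> first maximal row
    return GridSearchOutcome(
        best=grid[best_idx],
        tuning_subject_ids=tuple(s.subject_id for s in tuning_subjects),
        scores=scores,
    )
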