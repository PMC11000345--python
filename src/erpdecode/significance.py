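"""Permutation-based significance for decoding accuracies.

The null hypothesis is that emotion labels carry no information about the
single-trial waveforms. It is simulated by shuffling each subject's label
vector (features untouched) and re-running the identical cross-validation
pipeline; permutation r is one independent within-subject shuffle, and the
group-average null pairs the r-th shuffle across subjects, giving an
empirical null distribution of group-mean accuracies. An observed group
mean is declared significant when it exceeds the nearest-rank
(1 - alpha) quantile of that null (95th percentile at alpha = 0.05); the
add-one empirical p-value (Phipson-Smyth style) is reported alongside, so
p is never smaller than 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .decoding import CvConfig, RfConfig, cross_validated_accuracy
from .features import FeatureMatrix

#: signature of a pluggable accuracy pipeline (test hook / stand-in models)
AccuracyFn = Callable[[np.ndarray, np.ndarray], float]


@dataclass
class PermutationNull:
    """Per-subject permuted accuracies and the group-average null."""

    scheme: str
    n_perm: int
    per_subject: np.ndarray  # subjects x n_perm
    group_null: np.ndarray  # length n_perm
    alpha: float
    boundary: float

    @classmethod
    def from_per_subject(
        cls, per_subject_vectors: list[np.ndarray], alpha: float = 0.05, scheme: str = ""
    ) -> "PermutationNull":
        per_subject = np.vstack([np.asarray(v, dtype=float) for v in per_subject_vectors])
        null = group_null(list(per_subject))
        return cls(
            scheme=scheme,
            n_perm=per_subject.shape[1],
            per_subject=per_subject,
            group_null=null,
            alpha=alpha,
            boundary=significance_boundary(null, alpha),
        )


def _shuffled(labels: np.ndarray, seed: int, r: int) -> np.ndarray:
    rng = np.random.default_rng([seed, r])
    return labels[rng.permutation(labels.size)]


def permuted_accuracies(
    features: FeatureMatrix,
    cv: CvConfig = CvConfig(),
    rf: RfConfig = RfConfig(),
    n_perm: int = 200,
    seed: int = 0,
    accuracy_fn: AccuracyFn | None = None,
) -> np.ndarray:
    """Mean CV accuracy under ``n_perm`` uniform label shuffles.

    Shuffle r is seeded from ``(seed, r)``; the CV/forest pipeline (and its
    seeds) is identical to the observed analysis. ``accuracy_fn`` replaces
    the pipeline with an arbitrary ``(values, labels) -> accuracy`` stand-in,
    used for exhaustive-enumeration oracles in tests.
    """
    if n_perm < 0:
        raise ValueError("n_perm must be >= 0")
    out = np.empty(n_perm)
    for r in range(n_perm):
        labels = _shuffled(features.labels, seed, r + 1)
        if accuracy_fn is not None:
            out[r] = accuracy_fn(features.values, labels)
        else:
            fm = FeatureMatrix(
                values=features.values,
                feature_times=features.feature_times,
                labels=labels,
                scheme=features.scheme,
                class_names=features.class_names,
                trial_ids=features.trial_ids,
                subject_id=features.subject_id,
            )
            out[r] = cross_validated_accuracy(fm, cv, rf).mean_accuracy
    return out


def group_null(per_subject: list[np.ndarray]) -> np.ndarray:
    """Element r = unweighted mean over subjects of the r-th permuted
    accuracy (the group-average null distribution)."""
    if not per_subject:
        raise ValueError("need at least one subject")
    lengths = {np.asarray(v).size for v in per_subject}
    if len(lengths) != 1:
        raise ValueError(f"ragged per-subject null vectors (lengths {sorted(lengths)})")
    return np.vstack([np.asarray(v, dtype=float) for v in per_subject]).mean(axis=0)


def significance_boundary(null: np.ndarray, alpha: float = 0.05) -> float:
    """Nearest-rank (1 - alpha) quantile: the ceil((1-alpha)*n)-th order
    statistic of the null vector."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null vector")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rank = int(np.ceil((1.0 - alpha) * null.size))  # 1-based
    rank = min(max(rank, 1), null.size)
    return float(np.sort(null)[rank - 1])


def empirical_p(observed: float, null: np.ndarray) -> float:
    """Add-one empirical p-value: (1 + #{null >= observed}) / (1 + n)."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null vector")
    return float((1 + np.sum(null >= observed)) / (1 + null.size))
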