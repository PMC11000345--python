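"""From epochs to the classified feature representation.

Features are raw single-trial voltages at one electrode (Cz by default) on
the fixed post-onset time grid: sample k sits at t = k / sampling_rate, so a
2300 ms epoch at 256 Hz yields exactly 588 features (3.9 ... 2296.9 ms).
No baseline correction, detrending or normalisation is applied — trials are
classified on microvolt levels directly. When the target electrode is
missing it can be reconstructed as the unweighted mean of lateral
neighbours (C1/C2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import EMOTIONS, EpochSet

SCHEMES = ("multiclass", "happy-sad", "happy-neutral", "sad-neutral")


@dataclass
class FeatureMatrix:
    """Retained trials x time-point features for one classification scheme."""

    values: np.ndarray  # trials x features, uV
    feature_times: np.ndarray  # ms, length n_features
    labels: np.ndarray  # per-trial class label (str)
    scheme: str
    class_names: tuple[str, ...]
    trial_ids: np.ndarray  # original trial indices, for alignment checks
    subject_id: str = ""

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


def scheme_classes(scheme: str) -> tuple[str, ...]:
    if scheme == "multiclass":
        return EMOTIONS
    if scheme in SCHEMES:
        a, b = scheme.split("-")
        return (a, b)
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def interpolate_channel(
    epochs: EpochSet, target: str, sources: list[str]
) -> EpochSet:
    """Append ``target`` as the sample-wise arithmetic mean of ``sources``.

    The stand-in for a missing electrode: every sample of the new channel
    is the unweighted mean of the source channels' samples. Existing
    channels are untouched.
    """
    if target in epochs.channels:
        raise ValueError(f"target channel {target!r} already present")
    if not sources:
        raise ValueError("at least one source channel required")
    missing = [s for s in sources if s not in epochs.channels]
    if missing:
        raise KeyError(f"missing source channel(s) {missing}; have {epochs.channels}")
    src = np.stack([epochs.channel_data(s) for s in sources], axis=0)
    new = src.mean(axis=0)[:, None, :]
    return EpochSet(
        subject_id=epochs.subject_id,
        sampling_rate=epochs.sampling_rate,
        channels=list(epochs.channels) + [target],
        data=np.concatenate([epochs.data, new], axis=1),
        labels=epochs.labels,
        retained=epochs.retained,
    )


def build_feature_matrix(
    epochs: EpochSet,
    channel: str = "Cz",
    window: tuple[float, float] | None = None,
    scheme: str = "multiclass",
    exclude_catch: bool = True,
) -> FeatureMatrix:
    """One row per retained (and, by default, non-catch) trial of the
    channel's samples inside ``window`` (ms), labelled per ``scheme``.

    Binary schemes drop trials of the third emotion; feature values are
    never altered by the scheme, only row selection changes.
    """
    classes = scheme_classes(scheme)
    ci = epochs.channel_index(channel)
    t = epochs.time_grid()
    if window is None:
        col_mask = np.ones(t.size, dtype=bool)
    else:
        lo, hi = window
        if not lo < hi:
            raise ValueError("window start must precede end")
        col_mask = (t >= lo) & (t <= hi)
    if not col_mask.any():
        raise ValueError(f"window {window} selects no samples")

    keep = epochs.retained.copy()
    if exclude_catch and "catch" in epochs.labels.columns:
        keep &= ~epochs.labels["catch"].to_numpy()
    emotions = epochs.labels["emotion"].to_numpy()
    keep &= np.isin(emotions, classes)

    labels = emotions[keep]
    for c in classes:
        if not (labels == c).any():
            raise ValueError(f"class {c!r} has no trials after subsetting")

    trial_ids = (
        epochs.labels["trial"].to_numpy()[keep]
        if "trial" in epochs.labels.columns
        else np.flatnonzero(keep)
    )
    return FeatureMatrix(
        values=epochs.data[keep][:, ci, :][:, col_mask],
        feature_times=t[col_mask],
        labels=labels,
        scheme=scheme,
        class_names=classes,
        trial_ids=trial_ids,
        subject_id=epochs.subject_id,
    )
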