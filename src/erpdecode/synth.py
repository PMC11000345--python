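"""Synthetic evoked-potential cohorts with the emotion-oddity study design.

The generator emulates, at the epoched level, an auditory-emotion EEG
experiment: 48 stimuli (2 modalities x 3 emotions x 8 exemplars) each
repeated 15 times (720 trials), presented in randomised blocks of 48,
with 7% attention-check ("click") trials, and post-hoc trial rejection
that always leaves at least 5 of the 15 repetitions of every stimulus.

Single-trial waveforms are sums of Gaussian deflections (N100, P200, a
late positivity) plus white and 1/f ("pink") noise. Emotion enters through
an :class:`EmotionEffectProfile`: sad stimuli delay the N100/P200 latencies,
and emotional (happy/sad) stimuli carry an extra offset in a late
600-850 ms window. Setting ``effect_scale = 0`` removes every
label-dependent term, so the emotion label is statistically independent of
the signal — the basis of the type-I-error studies downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

EMOTIONS = ("happy", "sad", "neutral")
MODALITIES = ("voice", "music")

#: components whose latency is shifted on sad trials
_SHIFTED_COMPONENTS = frozenset({"N100", "P200"})


@dataclass(frozen=True)
class ErpComponent:
    """One evoked deflection, modelled as a Gaussian bump.

    Parameters
    ----------
    name : str
        Component label ("N100", "P200", ...). Components named N100 or
        P200 receive the sad-latency shift.
    amplitude : float
        Peak amplitude in microvolt; negative for N100.
    latency : float
        Peak time in ms from stimulus onset.
    width : float
        Gaussian SD of the deflection, ms.
    """

    name: str
    amplitude: float
    latency: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"component {self.name!r}: width must be > 0")
        if self.latency < 0:
            raise ValueError(f"component {self.name!r}: latency must be >= 0")


@dataclass(frozen=True)
class EmotionEffectProfile:
    """How emotion (and the listener group) shapes the waveform.

    ``attenuation`` and ``prolongation`` model group-level differences:
    cochlear-implant users' early responses are attenuated (< 1) and
    prolonged (> 1) relative to normal-hearing listeners.
    ``effect_scale`` multiplies every label-dependent term
    (``latency_shift_sad`` and ``late_offset``); at 0 the three emotions
    have identical expected waveforms.
    """

    latency_shift_sad: float = 20.0  # ms added to N100/P200 on sad trials
    late_offset: dict[str, float] = field(
        default_factory=lambda: {"happy": 1.0, "sad": 1.0, "neutral": 0.0}
    )
    late_window: tuple[float, float] = (600.0, 850.0)  # ms
    attenuation: float = 1.0
    prolongation: float = 1.0
    effect_scale: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.late_window
        if not lo < hi:
            raise ValueError("late_window start must precede end")
        if self.attenuation <= 0:
            raise ValueError("attenuation must be > 0")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be >= 0")


#: normal-hearing and cochlear-implant group profiles
PROFILES = {
    "NH": EmotionEffectProfile(),
    "CI": EmotionEffectProfile(attenuation=0.8, prolongation=1.1),
}


@dataclass(frozen=True)
class StudyDesign:
    """Trial bookkeeping of the experiment."""

    n_modalities: int = 2
    n_emotions: int = 3
    exemplars_per_cell: int = 8
    repetitions: int = 15
    catch_rate: float = 0.07
    sampling_rate: float = 256.0  # Hz
    epoch_ms: float = 2300.0
    n_samples: int = 588

    def __post_init__(self) -> None:
        if self.n_emotions != len(EMOTIONS):
            raise ValueError(f"n_emotions must be {len(EMOTIONS)} (labels {EMOTIONS})")
        if not 1 <= self.n_modalities <= len(MODALITIES):
            raise ValueError(f"n_modalities must be in 1..{len(MODALITIES)}")
        if not 0 <= self.catch_rate < 1:
            raise ValueError("catch_rate must be in [0, 1)")
        # the time grid (sample k at k/fs) must fit inside the epoch
        if self.n_samples * 1000.0 / self.sampling_rate > self.epoch_ms + 1e-9:
            raise ValueError("n_samples * (1000/sampling_rate) exceeds epoch_ms")

    @property
    def n_stimuli(self) -> int:
        return self.n_modalities * self.n_emotions * self.exemplars_per_cell

    @property
    def n_trials(self) -> int:
        return self.n_stimuli * self.repetitions

    def time_grid(self) -> np.ndarray:
        """Sample times in ms: sample k (1-based) at t = k / sampling_rate."""
        return np.arange(1, self.n_samples + 1) * (1000.0 / self.sampling_rate)

    def stimulus_table(self) -> pd.DataFrame:
        """One row per distinct stimulus: stim_id, modality, emotion, exemplar."""
        rows = []
        sid = 0
        for m in range(self.n_modalities):
            for e in range(self.n_emotions):
                for x in range(self.exemplars_per_cell):
                    rows.append(
                        {
                            "stim_id": sid,
                            "modality": MODALITIES[m],
                            "emotion": EMOTIONS[e],
                            "exemplar": x,
                        }
                    )
                    sid += 1
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class RejectionModel:
    """Artifact-driven trial rejection: how many trials drop, and the floor."""

    mean_rejected: float = 40.0
    sd_rejected: float = 32.0
    min_per_stimulus: int = 5

    def __post_init__(self) -> None:
        if self.mean_rejected < 0:
            raise ValueError("mean_rejected must be >= 0")
        if self.sd_rejected < 0:
            raise ValueError("sd_rejected must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Trial- and subject-level variability, all in microvolt / ms units.

    ``white_sd`` and ``pink_sd`` are per-sample SDs of the white and
    1/f-shaped trial noise. ``subject_amp_sd`` / ``subject_lat_sd`` are SDs
    of between-subject additive offsets on each component's amplitude and
    latency. All zero means every trial of an emotion is the identical
    noiseless waveform.
    """

    white_sd: float = 2.0
    pink_sd: float = 2.0
    subject_amp_sd: float = 0.5
    subject_lat_sd: float = 5.0

    def __post_init__(self) -> None:
        for f_ in ("white_sd", "pink_sd", "subject_amp_sd", "subject_lat_sd"):
            if getattr(self, f_) < 0:
                raise ValueError(f"{f_} must be >= 0")


DEFAULT_COMPONENTS = (
    ErpComponent("N100", -5.0, 100.0, 20.0),
    ErpComponent("P200", 6.0, 200.0, 30.0),
    ErpComponent("late", 2.0, 725.0, 80.0),
)


@dataclass
class EpochSet:
    """A subject's epoched trials: data (trials x channels x samples, uV),
    per-trial labels, and a retention mask."""

    subject_id: str
    sampling_rate: float
    channels: list[str]
    data: np.ndarray
    labels: pd.DataFrame
    retained: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.retained = np.asarray(self.retained, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("data first dimension must equal label count")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("data second dimension must equal channel count")
        if self.retained.shape != (self.data.shape[0],):
            raise ValueError("retained mask must be one flag per trial")
        bad = set(self.labels["emotion"]) - set(EMOTIONS)
        if bad:
            raise ValueError(f"unknown emotion labels: {sorted(bad)}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"channel {channel!r} not present (have {self.channels})")

    def channel_data(self, channel: str) -> np.ndarray:
        """Trials x samples view of one channel."""
        return self.data[:, self.channel_index(channel), :]

    def time_grid(self) -> np.ndarray:
        return np.arange(1, self.n_samples + 1) * (1000.0 / self.sampling_rate)


def erp_waveform(
    components: list[ErpComponent] | tuple[ErpComponent, ...],
    effect: EmotionEffectProfile,
    emotion: str,
    time_grid: np.ndarray,
) -> np.ndarray:
    """Noiseless single-condition waveform on ``time_grid`` (ms), in uV.

    Sum over components of Gaussian bumps
    ``amplitude * attenuation * exp(-(t - mu)^2 / (2 width^2))`` with
    ``mu = latency * prolongation (+ sad shift for N100/P200)``, plus the
    emotion's late-window offset.
    """
    if emotion not in EMOTIONS:
        raise ValueError(f"unknown emotion {emotion!r}; expected one of {EMOTIONS}")
    t = np.asarray(time_grid, dtype=np.float64)
    if t.ndim != 1 or (t.size > 1 and not np.all(np.diff(t) > 0)):
        raise ValueError("time_grid must be strictly increasing 1-D")
    out = np.zeros_like(t)
    shift = effect.latency_shift_sad * effect.effect_scale if emotion == "sad" else 0.0
    for c in components:
        mu = c.latency * effect.prolongation
        if c.name in _SHIFTED_COMPONENTS:
            mu += shift
        out += (c.amplitude * effect.attenuation) * np.exp(
            -((t - mu) ** 2) / (2.0 * c.width**2)
        )
    lo, hi = effect.late_window
    offset = effect.late_offset.get(emotion, 0.0) * effect.effect_scale
    if offset != 0.0:
        out[(t >= lo) & (t <= hi)] += offset
    return out


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float) -> np.ndarray:
    """1/f-shaped Gaussian noise with per-trial sample SD ``sd``."""
    if sd == 0.0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(shape[-1])
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    pink = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    std = pink.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return sd * pink / std


def _subject_components(
    components: tuple[ErpComponent, ...],
    noise: NoiseModel,
    rng: np.random.Generator,
) -> tuple[ErpComponent, ...]:
    """Perturb component amplitudes/latencies with subject-level offsets."""
    out = []
    for c in components:
        d_amp = rng.normal(0.0, noise.subject_amp_sd) if noise.subject_amp_sd else 0.0
        d_lat = rng.normal(0.0, noise.subject_lat_sd) if noise.subject_lat_sd else 0.0
        out.append(replace(c, amplitude=c.amplitude + d_amp, latency=max(0.0, c.latency + d_lat)))
    return tuple(out)


def _max_feasible_rejections(labels: pd.DataFrame, retained: np.ndarray, floor: int) -> int:
    counts = labels.loc[retained, "stim_id"].value_counts()
    return int(np.maximum(counts - floor, 0).sum())


def apply_trial_rejection(
    epochs: EpochSet, rejection: RejectionModel, seed: int
) -> EpochSet:
    """Mark trials not-retained, mimicking artifact rejection.

    Draws the rejection count from a normal truncated to
    ``[0, max feasible]`` and rejects that many trials uniformly at random,
    never letting any stimulus drop below ``min_per_stimulus`` retained
    trials. Labels and data are untouched; only the mask changes.
    """
    rng = np.random.default_rng(seed)
    retained = epochs.retained.copy()
    max_feasible = _max_feasible_rejections(epochs.labels, retained, rejection.min_per_stimulus)
    if rejection.mean_rejected > max_feasible:
        raise ValueError(
            f"rejection infeasible: mean_rejected={rejection.mean_rejected} exceeds the "
            f"{max_feasible} trials removable while keeping >= "
            f"{rejection.min_per_stimulus} per stimulus"
        )
    if rejection.sd_rejected == 0.0:
        n_reject = int(round(min(rejection.mean_rejected, max_feasible)))
    else:
        a = (0.0 - rejection.mean_rejected) / rejection.sd_rejected
        b = (max_feasible - rejection.mean_rejected) / rejection.sd_rejected
        draw = stats.truncnorm.rvs(
            a, b, loc=rejection.mean_rejected, scale=rejection.sd_rejected, random_state=rng
        )
        n_reject = int(np.clip(round(draw), 0, max_feasible))
    if n_reject == 0:
        return replace_mask(epochs, retained)

    counts = epochs.labels.loc[retained, "stim_id"].value_counts().to_dict()
    order = rng.permutation(np.flatnonzero(retained))
    stim = epochs.labels["stim_id"].to_numpy()
    rejected = 0
    for idx in order:
        if rejected == n_reject:
            break
        s = stim[idx]
        if counts[s] > rejection.min_per_stimulus:
            retained[idx] = False
            counts[s] -= 1
            rejected += 1
    return replace_mask(epochs, retained)


def replace_mask(epochs: EpochSet, retained: np.ndarray) -> EpochSet:
    return EpochSet(
        subject_id=epochs.subject_id,
        sampling_rate=epochs.sampling_rate,
        channels=list(epochs.channels),
        data=epochs.data,
        labels=epochs.labels,
        retained=retained,
    )


def generate_subject(
    design: StudyDesign,
    components: tuple[ErpComponent, ...] = DEFAULT_COMPONENTS,
    effect: EmotionEffectProfile = PROFILES["CI"],
    noise: NoiseModel = NoiseModel(),
    rejection: RejectionModel | None = RejectionModel(),
    seed: int = 0,
    subject_id: str | None = None,
    channels: tuple[str, ...] = ("Cz",),
) -> EpochSet:
    """Simulate one subject's epoched trials.

    One trial per (stimulus, repetition), presentation order randomised
    within each block of ``n_stimuli`` trials; waveform + white + pink noise
    per trial and channel; ``floor(catch_rate * n_trials)`` trials flagged
    as attention checks; rejection applied last. Identical seeds give
    bit-identical outputs.
    """
    rng = np.random.default_rng(seed)
    subj_components = _subject_components(components, noise, rng)
    stim_table = design.stimulus_table()
    t = design.time_grid()

    cond_wave = {
        e: erp_waveform(subj_components, effect, e, t) for e in EMOTIONS[: design.n_emotions]
    }

    # presentation order: each block holds every stimulus once, shuffled
    blocks = [rng.permutation(design.n_stimuli) for _ in range(design.repetitions)]
    order = np.concatenate(blocks)
    rep_index = np.repeat(np.arange(design.repetitions), design.n_stimuli)

    labels = stim_table.iloc[order].reset_index(drop=True)
    labels["repetition"] = rep_index
    n = design.n_trials
    catch = np.zeros(n, dtype=bool)
    n_catch = int(np.floor(design.catch_rate * n))
    if n_catch:
        catch[rng.choice(n, size=n_catch, replace=False)] = True
    labels["catch"] = catch
    labels["trial"] = np.arange(n)

    base = np.stack([cond_wave[e] for e in labels["emotion"]])  # trials x samples
    data = np.empty((n, len(channels), design.n_samples))
    for ci in range(len(channels)):
        white = rng.normal(0.0, noise.white_sd, size=(n, design.n_samples)) if noise.white_sd else 0.0
        pink = _pink_noise(rng, (n, design.n_samples), noise.pink_sd)
        data[:, ci, :] = base + white + pink

    epochs = EpochSet(
        subject_id=subject_id or f"sub-{seed:03d}",
        sampling_rate=design.sampling_rate,
        channels=list(channels),
        data=data,
        labels=labels,
        retained=np.ones(n, dtype=bool),
    )
    if rejection is not None:
        rej_seed = int(rng.integers(2**31))
        epochs = apply_trial_rejection(epochs, rejection, rej_seed)
    return epochs


def generate_cohort(
    n_subjects: int,
    design: StudyDesign = StudyDesign(),
    components: tuple[ErpComponent, ...] = DEFAULT_COMPONENTS,
    effect: EmotionEffectProfile = PROFILES["CI"],
    noise: NoiseModel = NoiseModel(),
    rejection: RejectionModel | None = RejectionModel(),
    seed: int = 0,
    channels: tuple[str, ...] = ("Cz",),
) -> list[EpochSet]:
    """Simulate ``n_subjects`` independent subjects.

    Subject i uses seed ``seed + i`` (documented scheme), so cohorts are
    reproducible subject-by-subject and extending the cohort does not
    change earlier subjects.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return [
        generate_subject(
            design,
            components=components,
            effect=effect,
            noise=noise,
            rejection=rejection,
            seed=seed + i,
            subject_id=f"sub-{i + 1:03d}",
            channels=channels,
        )
        for i in range(n_subjects)
    ]
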