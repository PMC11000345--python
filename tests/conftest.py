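import numpy as np
import pytest

from erpdecode import (
    EmotionEffectProfile,
    NoiseModel,
    StudyDesign,
    generate_subject,
)

# 2 x 3 x 2 x 5 = 60 trials, 64 samples at 64 Hz (grid spans 1000 ms,
# covering the 600-850 ms late window) — fast but structurally faithful
SMALL = dict(exemplars_per_cell=2, repetitions=5, catch_rate=0.0,
             sampling_rate=64.0, n_samples=64, epoch_ms=1000.0)


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign(**SMALL)


@pytest.fixture(scope="session")
def small_subject(small_design):
    """One small noisy subject with the default (unit) emotion effect."""
    return generate_subject(small_design, seed=7, rejection=None)


@pytest.fixture(scope="session")
def clean_subject(small_design):
    """Noise-free subject: every trial of an emotion is the exact waveform."""
    return generate_subject(
        small_design,
        noise=NoiseModel(0.0, 0.0, 0.0, 0.0),
        rejection=None,
        seed=3,
    )


@pytest.fixture(scope="session")
def null_subject(small_design):
    """Subject with effect_scale 0: labels independent of the signal."""
    return generate_subject(
        small_design,
        effect=EmotionEffectProfile(effect_scale=0.0),
        rejection=None,
        seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
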