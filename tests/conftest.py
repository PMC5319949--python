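import numpy as np
import pytest

import eegfam


@pytest.fixture(scope="session")
def music_recs():
    """Small music-geometry session: 2 subjects x 4 songs x 24 s."""
    spec = eegfam.SessionSpec.music12(
        n_subjects=2, n_stimuli_per_subject=4, stimulus_duration=24.0, seed=11
    )
    return eegfam.simulate_session(spec)


@pytest.fixture(scope="session")
def music_table(music_recs):
    return eegfam.assemble_feature_table(music_recs, eegfam.FeatureConfig("music12"))


@pytest.fixture(scope="session")
def video_recs():
    """Small video-geometry session: 2 subjects x 4 trials x 20 s."""
    spec = eegfam.SessionSpec.video32(
        n_subjects=2, n_stimuli_per_subject=4, stimulus_duration=20.0, seed=12
    )
    return eegfam.simulate_session(spec)


@pytest.fixture(scope="session")
def video_table(video_recs):
    return eegfam.assemble_feature_table(video_recs, eegfam.FeatureConfig("video32"))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def sine_recording(freq, rate=250.0, seconds=8.0, amplitude=1.0, channels=("Cz",)):
    """Single-tone Recording helper used across filter tests."""
    import pandas as pd

    n = int(rate * seconds)
    t = np.arange(n) / rate
    x = amplitude * np.sin(2 * np.pi * freq * t)
    ann = pd.DataFrame({"t": [0.0], "valence": [0.5], "arousal": [0.5]})
    return eegfam.Recording(
        samples=np.tile(x, (len(channels), 1)),
        rate=rate,
        channels=channels,
        subject_id="S01",
        stimulus_id="T01",
        familiarity=6,
        annotations=ann,
    )
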