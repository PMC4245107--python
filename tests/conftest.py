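import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import storyenc as se

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_story():
    """Four RSVP words, two features, two named sets."""
    return se.AnnotatedStory(
        words=["the", "boy", "flew", "home"],
        onsets=np.array([0.0, 0.5, 1.0, 1.5]),
        features=np.array([[5.0, 1.0], [3.0, 0.0], [4.0, 0.0], [2.0, 1.0]]),
        feature_names=["word_length", "is_noun"],
        feature_sets={"visual": ["word_length"], "syntax": ["is_noun"]},
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale 2-subject simulation at SNR 1 used by several suites."""
    story, subjects, truth = se.default_scenario(
        seed=3, snr=1.0, T=200, n_voxels=50, n_subjects=2, n_features=6)
    return story, subjects, truth
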