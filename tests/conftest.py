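"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from kinstyle import kinfeat, synthkin


@pytest.fixture(scope="session")
def style_profiles():
    """Nine participants in three well-separated style groups."""
    profiles, truth = synthkin.gen_styles(
        n_participants=9, n_style_groups_per_intent=3, separation=6.0,
        seed=11)
    return profiles, truth


@pytest.fixture(scope="session")
def pour_trials(style_profiles):
    """Session-2 pour trials for the style-group participants."""
    profiles, _ = style_profiles
    return synthkin.gen_dataset(profiles, trials_per_intent_per_session=6,
                                sessions=(2,), seed=12, intents=("pour",))

@pytest.fixture(scope="session")
def pour_features(pour_trials):
    return kinfeat.build_feature_matrix(pour_trials)


@pytest.fixture(scope="session")
def clean_trial():
    """One noise-free trial: deterministic kinematic template."""
    profile = synthkin.StyleProfile(
        "P01", {"pour": {"peak_aperture_mm": 0.0, "finger_tilt_deg": 0.0}},
        noise_sd=0.0, marker_noise_sd=0.0)
    return synthkin.gen_trial(profile, "pour", duration_s=1.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
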