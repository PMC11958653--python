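
import numpy as np
import pytest

from cogload import synthetic as syn


def small_effects() -> syn.ConditionEffects:
    """Default condition effects with shortened repetition durations.

    Keeps all effect directions and questionnaire distributions at
    their defaults while holding the task sessions near the one-minute
    floor so signal synthesis stays cheap in unit tests.
    """
    return syn.ConditionEffects(
        rep_duration_mean_s={"visual": 10.0, "code": 16.0},
    )


@pytest.fixture(scope="session")
def small_study() -> syn.SyntheticStudy:
    """Four participants (one per subgroup), 50 Hz, 60-s sessions."""
    config = syn.StudyConfig(
        n_participants=4,
        fs=50.0,
        session_length_s=60.0,
        baseline_length_s=60.0,
        seed=11,
        effects=small_effects(),
    )
    return syn.generate_study(config)


@pytest.fixture(scope="session")
def behavioural_study() -> syn.SyntheticStudy:
    """Thirty participants at the default study conditions, signals omitted."""
    config = syn.StudyConfig(n_participants=30, seed=5)
    return syn.generate_study(config, include_signals=False)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
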