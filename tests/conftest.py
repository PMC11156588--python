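import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def short_annotation():
    """A 10-min annotation at the default grooming statistics."""
    from pregroom import BehaviorModel, simulate_behavior

    return simulate_behavior(BehaviorModel(), seed=7)


@pytest.fixture(scope="session")
def small_recording(short_annotation):
    """A 4-channel LFP for the 10-min annotation at 250 Hz (fast to analyze)."""
    from pregroom import BiomarkerModel, simulate_lfp

    return simulate_lfp(
        short_annotation, BiomarkerModel(rate_hz=250.0), n_channels=4, seed=8
    )


@pytest.fixture(scope="session")
def event_train_annotation():
    """A designed annotation with many regularly spaced grooming events."""
    from pregroom.signal_io import BehaviorAnnotation, BehaviorEvent

    n, spacing = 60, 14.0
    events = [
        BehaviorEvent("grooming", 10 + i * spacing, 14 + i * spacing) for i in range(n)
    ]
    return BehaviorAnnotation(events, 10 + n * spacing + 10)
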