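import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_measurements():
    """Small synthetic dataset shared by the preprocessing tests."""
    from ripetap.synthetic import generate_dataset

    return generate_dataset(n_fruits=4, measurement_days=(0, 7, 14, 21),
                            zones=(1, 2, 3), repeats=1, seed=42,
                            n_samples=2048)


def burst_tone(fs=44_100, seconds=2.0, freq=430.66, decay=30.0,
               onsets=(0.2, 0.7, 1.2, 1.7)):
    """Tap-like damped tone bursts: the transient signal class the
    minimum-statistics noise tracker is designed for."""
    t = np.arange(int(seconds * fs)) / fs
    clean = np.zeros_like(t)
    for onset in onsets:
        tau = np.clip(t - onset, 0.0, None)
        clean += np.exp(-decay * tau) * np.sin(2 * np.pi * freq * tau) * (tau > 0)
    return 0.5 * clean
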