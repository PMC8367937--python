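import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_kalman_records():
    """A small but non-trivial Kalman population run (20 subjects x 168)."""
    from durdisc import pipeline

    config = pipeline.RunConfig(models=("kalman",), n_subjects=20,
                                n_trials=168, seed=42)
    return pipeline.simulate_records("kalman", config)
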