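import hypothesis
import numpy as np
import pytest

from headtrack.observer import ObserverConfig, simulate_observer
from headtrack.stimulus import GeneratorConfig, generate_heading_path

hypothesis.settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=100
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_trajectory():
    """One 90 s random-walk trajectory at the experiment's parameters."""
    return generate_heading_path(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def pure_delay_recording(default_trajectory):
    """Noise-free observer with a 1.0 s response lag: the response is an
    exact delayed copy of the stimulus."""
    obs = ObserverConfig(R_deg2=0.0, lag_s=1.0, motor_sd_deg=0.0, seed=7)
    return simulate_observer(default_trajectory, obs)


@pytest.fixture(scope="session")
def noisy_recording(default_trajectory):
    """Observer with sensory noise only (R = 100 deg^2), matched 1 s lag."""
    obs = ObserverConfig(R_deg2=100.0, lag_s=1.0, motor_sd_deg=0.0, seed=13)
    return simulate_observer(default_trajectory, obs, Q_deg2=400.0)
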