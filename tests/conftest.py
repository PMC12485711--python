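import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fiberfeed as ff

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def small_recording(rng):
    """60 s two-channel recording at 10 Hz with mild shared artifact."""
    t = np.arange(600) / 10.0
    artifact = np.sin(t)
    f_ca = 100.0 + 2.0 * artifact + rng.normal(0, 0.5, len(t))
    f_iso = 50.0 + 1.6 * artifact + rng.normal(0, 0.5, len(t))
    return ff.RawRecording(t=t, f_ca=f_ca, f_iso=f_iso, sample_rate=10.0)


@pytest.fixture
def fast_session():
    """One noiseless-latent fast session rendered with default noise."""
    state = ff.simulate_latent_state(ff.StateParams(), "fast", 12.5, 10.0, 3)
    rec, truth = ff.simulate_photometry(state, ff.PhotometryNoiseParams(), 3)
    return rec, truth
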