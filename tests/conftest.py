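import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_spd():
    """Factory for random symmetric positive-definite matrices."""

    def make(k, seed=0, cond_boost=0.0):
        r = np.random.default_rng(seed)
        X = r.standard_normal((k, 3 * k))
        C = X @ X.T
        if cond_boost:
            C += cond_boost * np.eye(k)
        return C

    return make


@pytest.fixture
def single_dipole_recording():
    """Seeded 24-channel recording with one planted burst dipole at SNR 10.

    Returns (y, lead_fields, activity, spec, config); noise sigma is the
    peak noiseless sensor amplitude divided by 10 (amplitude-ratio SNR 10).
    """
    from alcmv import SimulationConfig, SourceSpec, simulate_recording

    rng = np.random.default_rng(101)
    eta = rng.standard_normal(3)
    eta /= np.linalg.norm(eta)
    spec = SourceSpec(location_index=0, orientation=eta, waveform="burst")
    noiseless = SimulationConfig(
        k=24, N=2000, fs=250.0, noise_sigma=0.0, seed=1, sources=[spec]
    )
    y0, _, _ = simulate_recording(noiseless)
    config = SimulationConfig(
        k=24, N=2000, fs=250.0, noise_sigma=float(np.abs(y0).max() / 10.0),
        seed=1, sources=[spec],
    )
    y, lead_fields, activity = simulate_recording(config)
    return y, lead_fields, activity, spec, config
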