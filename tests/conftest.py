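import numpy as np
import pytest

from roflpli import AcquisitionConfig, MeasurementSeries, PixelParams
from roflpli import noise as noise_mod
from roflpli.forward_model import simulate_series


@pytest.fixture(scope="session")
def acq() -> AcquisitionConfig:
    """Standard acquisition: 18 x 10 deg steps, planar + 4 tilts, I=2500, g=3."""
    return AcquisitionConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def make_series(acq):
    """Factory for single-pixel measurement series (optionally noisy)."""

    def _make(phi_deg, alpha_deg, d, noisy=False, seed=0, acq_=None):
        a = acq_ or acq
        p = PixelParams(np.deg2rad(phi_deg), np.deg2rad(alpha_deg), d)
        clean = simulate_series(p, a)
        if noisy:
            clean = noise_mod.sample_counts(clean, a.gain, np.random.default_rng(seed))
        return MeasurementSeries(clean, a.tilt_states, a.rho)

    return _make
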