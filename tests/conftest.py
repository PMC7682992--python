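import numpy as np
import pytest

from thetalink import circuit as C
from thetalink import features as F

FS = 2000.0

THETA = F.BandSpec("Theta", 4.0, 12.0)
ALPHA = F.BandSpec("Alpha", 6.0, 10.0)
HIGH_GAMMA = F.BandSpec("HighGamma", 65.0, 100.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def theta_noise(duration: float, fs: float = FS, seed: int = 0,
                f0: float = 8.0, drift_sd: float = 3.0):
    """Narrowband theta-like process: drifting-phase cosine (phase, signal)."""
    g = np.random.default_rng(seed)
    n = int(duration * fs)
    phase = 2 * np.pi * f0 * np.arange(n) / fs + np.cumsum(
        g.standard_normal(n)) * drift_sd * np.sqrt(1 / fs)
    return phase, np.cos(phase)


@pytest.fixture(scope="session")
def calibrated_params():
    """Circuit weights realizing the (20, 25, 50) Hz operating point.

    Session-scoped: the coordinate-bisection search is the expensive part
    and every circuit test can share one parameterization.
    """
    return C.calibrate_operating_point(
        C.OperatingPoint(20.0, 25.0, 50.0), C.InputSpec(),
        seed=11, n_iter_search=150)
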