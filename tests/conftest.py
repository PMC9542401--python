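import numpy as np
import pytest

from splitpin import (
    PhasorCalibration,
    PinholeStack,
    SimulationConfig,
    simulate_stack,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_sim_config():
    """Cheap simulation: small grid, few emitters, noise off."""
    return SimulationConfig(grid=(64, 64), n_emitters=3, S=100.0,
                            noise="none", seed=42)


@pytest.fixture
def noiseless_stack(small_sim_config):
    stack, closed = simulate_stack(small_sim_config)
    return stack, closed


@pytest.fixture
def default_calibration():
    return PhasorCalibration.simulation_default()


def brute_force_acf(pixels: np.ndarray) -> np.ndarray:
    """Direct double-loop circular autocorrelation oracle.

    G(dz, dx) = <I(z, x) I(z+dz, x+dx)> / <I>^2 - 1 with periodic wrap,
    averaged over all pixels.  Independent of the FFT path it checks.
    """
    h, w = pixels.shape
    mean = pixels.mean()
    out = np.empty((h, w))
    for dz in range(h):
        for dx in range(w):
            shifted = np.roll(np.roll(pixels, -dz, axis=0), -dx, axis=1)
            out[dz, dx] = (pixels * shifted).mean() / mean**2 - 1.0
    return out


def stack_from_profiles(profile_maps: np.ndarray, sizes=(1.5, 1.0, 0.5)):
    """Build a PinholeStack directly from per-pixel frame profiles."""
    return PinholeStack(frames=profile_maps, pinhole_sizes=sizes)
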