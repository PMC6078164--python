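import numpy as np
import pytest

from circaomics.core import TimeGrid
from circaomics.rhythm import make_reference_waveforms
from circaomics.simulate import SimulationConfig, simulate_layer


@pytest.fixture(scope="session")
def grid():
    """The standard design: CT24-CT81 sampled every 3 h, one replicate."""
    return TimeGrid.regular(24, 81, 3)


@pytest.fixture(scope="session")
def waveforms(grid):
    """Default reference lattice (periods 21-27 h, 3-h steps)."""
    return make_reference_waveforms(grid)


@pytest.fixture(scope="session")
def small_rhythmic_layer():
    """A modest planted-rhythm layer shared by several tests."""
    cfg = SimulationConfig(
        n_features=300, fraction_rhythmic=0.2, noise_sd=0.1, seed=11
    )
    matrix, truth = simulate_layer(cfg)
    return cfg, matrix, truth


def cosine_profile(times, phase_h, amplitude_ratio=2.0, period_h=24.0,
                   baseline=10.0):
    """Noiseless positive-scale cosine used as a planted signal."""
    log_amp = np.log(amplitude_ratio) / 2.0
    return baseline * np.exp(
        log_amp * np.cos(2 * np.pi * (np.asarray(times) - phase_h) / period_h)
    )
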