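"""Shared fixtures: compact simulated acquisitions reused across tests."""

import numpy as np
import pytest

from periscat.simulate import SimulationConfig


@pytest.fixture(scope="session")
def xrd_config():
    """Compact noise-free 15 keV wide-angle geometry (320 px detector).

    The HAp (002) ring lands at ~147 px with a ~1.8 px FWHM; small enough
    that per-frame simulation costs milliseconds.
    """
    return SimulationConfig(energy_kev=15.0, detector_shape=(320, 320),
                            pixel_size_um=75.0,
                            sample_detector_distance_mm=45.0,
                            noise=False, seed=0)


@pytest.fixture(scope="session")
def strain_config():
    """Compact 17 keV geometry for indentation frames (ring at ~115 px)."""
    return SimulationConfig(energy_kev=17.0, detector_shape=(256, 256),
                            pixel_size_um=75.0,
                            sample_detector_distance_mm=40.0,
                            noise=False, seed=0)


@pytest.fixture(scope="session")
def strain_config_noisy(strain_config):
    return SimulationConfig(energy_kev=17.0, detector_shape=(256, 256),
                            pixel_size_um=75.0,
                            sample_detector_distance_mm=40.0,
                            noise=True, seed=7)


@pytest.fixture(scope="session")
def saxs_q_grid():
    """Default SAXS momentum-transfer grid, well into the Porod regime."""
    return np.linspace(0.01, 5.0, 1000)
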