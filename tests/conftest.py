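"""Shared fixtures: small sensor arrays and recordings, generated on the fly."""

import numpy as np
import pytest

import neotag as nt


@pytest.fixture(scope="session")
def small_array():
    """12 sensors (6 triaxial) on a 65 mm head: 30 channels."""
    return nt.make_sensor_array(12, 0.065, 6, seed=7)


@pytest.fixture(scope="session")
def desk_sim():
    """Desk-scale simulation parameters: 60 s at 300 Hz, 12 sensors."""
    return nt.SimulationConfig(duration=60.0, sampling_rate=300.0,
                               n_sensors=12, triaxial_count=6, seed=11)


@pytest.fixture()
def flat_recording(small_array):
    """All-zero 20 s recording over the small array."""
    n = int(20 * 300)
    return nt.Recording(300.0, small_array,
                        np.zeros((len(small_array), n)))


def make_noise_recording(channels, duration=30.0, fs=300.0, sigma=1.0,
                         seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    return nt.Recording(fs, channels,
                        rng.normal(0.0, sigma, (len(channels), n)))
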