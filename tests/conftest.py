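import warnings

import numpy as np
import pytest

from bundlerheo import (
    DriveProtocol,
    ImagingConfig,
    default_rod,
    render_stack,
)


@pytest.fixture(scope="session")
def rod():
    return default_rod()


@pytest.fixture(scope="session")
def noiseless_config():
    return ImagingConfig(shot_noise=False, read_noise_sd=0.0, bleach_rate=0.0)


@pytest.fixture(scope="session")
def default_config():
    return ImagingConfig(rng_seed=7)


@pytest.fixture(scope="session")
def drive_07hz():
    return DriveProtocol.for_camera(amplitude=1e-6, frequency_hz=0.7, n_periods=5)


@pytest.fixture(scope="session")
def noiseless_stack(rod, drive_07hz, noiseless_config):
    return render_stack(rod, drive_07hz, noiseless_config)


@pytest.fixture(scope="session")
def noisy_stack(rod, drive_07hz, default_config):
    return render_stack(rod, drive_07hz, default_config)


@pytest.fixture()
def suppress_tracking_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def gaussian_column(center: float, height: float = 200.0, sigma: float = 1.5,
                    background: float = 20.0, n: int = 64) -> np.ndarray:
    """A synthetic single-column line profile."""
    y = np.arange(n)
    return background + height * np.exp(-((y - center) ** 2) / (2 * sigma**2))
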