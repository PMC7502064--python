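import numpy as np
import pytest
from hypothesis import settings

import octforce as of

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def uniform_chirp() -> of.ChirpMap:
    return of.default_chirp(distortion=0.0)


@pytest.fixture(scope="session")
def chirped_map() -> of.ChirpMap:
    return of.default_chirp(distortion=0.15)


@pytest.fixture(scope="session")
def noiseless_needle() -> of.NeedleModel:
    return of.default_needle(noise_sd=0.0, drift_amplitude=0.0)


@pytest.fixture(scope="session")
def ramp_dataset(noiseless_needle, uniform_chirp) -> of.CalibrationDataset:
    """Noiseless single up/down ramp, 3000 scans: the round-trip workhorse."""
    return of.generate_dataset(
        noiseless_needle,
        uniform_chirp,
        3000,
        seed=11,
        n_ramps=1,
        peak_jitter=0.0,
        sensor_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def ramp_recon(ramp_dataset) -> np.ndarray:
    """Reconstructed A-scans (512 x 3000) of the noiseless ramp."""
    return of.reconstruct_mscan(ramp_dataset.mscan).ascans
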