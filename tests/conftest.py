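import numpy as np
import pytest

from frcrestore import ImageData
from frcrestore.calibrate import calibration_series
from frcrestore.frc import fit_calibration
from frcrestore.synthetic import AcquisitionSpec, simulate_pair


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_image(rng):
    return ImageData(rng.uniform(0.0, 100.0, (32, 32)), (50.0, 50.0))


@pytest.fixture(scope="session")
def sim_pair():
    """Default simulated acquisition: filaments, 50 nm pixels, 250 nm
    FWHM, 200 peak photons, two independent Poisson realizations."""
    spec = AcquisitionSpec(seed=11)
    phantom, (a, b) = simulate_pair(spec)
    return phantom, a, b


@pytest.fixture(scope="session")
def calibration():
    """One-image FRC calibration fitted on a small synthetic series."""
    return fit_calibration(calibration_series(n_scenes=1, seed=5))
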