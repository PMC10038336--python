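import numpy as np
import pytest
from hypothesis import settings

import frlap

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def lattice13():
    return frlap.build_nanotube(n_protomers=13)


@pytest.fixture(scope="session")
def spectra():
    return frlap.default_spectra()


@pytest.fixture(scope="session")
def calibrated():
    """Calibrated 13-protomer model; shared because the calibration
    root-find is the most expensive fixture in the suite."""
    return frlap.calibrated_model(n_protomers=13)


@pytest.fixture(scope="session")
def headline_ta_dataset():
    """The headline synthetic TA dataset (seed 1, 1% noise)."""
    from frlap import synth
    return frlap.synth.simulate_ta(
        synth.measured_ta_scheme(), synth.measured_ta_species(),
        synth.NoiseSpec(amplitude=1.0, seed=1))
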