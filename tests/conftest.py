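import pytest

from thioscan.profile_hmm import calibrate_library
from thioscan.synthetic_data import fixture_library


@pytest.fixture(scope="session")
def library():
    """Uncalibrated fixture profile library (deterministic)."""
    return fixture_library()


@pytest.fixture(scope="session")
def calibrated_library(library):
    """Fixture library with Gumbel calibration (seed fixed for the session)."""
    return calibrate_library(library, seed=1)
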