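import numpy as np
import pytest

from odcal.forward_model import MultipleScatteringParams, PathConfig
from odcal.scattering import OpticalContext, Scatterer


@pytest.fixture(scope="session")
def water() -> OpticalContext:
    return OpticalContext(wavelength_nm=600.0, n_medium=1.333)


@pytest.fixture(scope="session")
def bead_1um() -> Scatterer:
    """The ~1 µm polystyrene bead used throughout the reference data."""
    return Scatterer(diameter_um=0.96, n_particle=1.59)


@pytest.fixture(scope="session")
def path_1cm() -> PathConfig:
    return PathConfig(path_length_cm=1.0)


@pytest.fixture(scope="session")
def ms_params() -> MultipleScatteringParams:
    return MultipleScatteringParams(quad_coeff=0.1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20161213)
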