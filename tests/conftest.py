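import numpy as np
import pytest

from irco2kin import (
    FilmKinetics,
    GasProgram,
    NoiseModel,
    load_band_library,
    shift_templates,
)


@pytest.fixture(scope="session")
def band_library():
    return load_band_library()


@pytest.fixture(scope="session")
def reference_templates(band_library):
    """12C / H2O / local_KsCcr templates without the bulk-water component."""
    tpl = shift_templates(band_library)
    tpl.pop("bulk_water")
    return tpl


@pytest.fixture
def step10_program():
    """10% CO2 switched on at t=10 s after an N2 baseline."""
    return GasProgram(steps=((0.0, 0.0, "N2"), (10.0, 10.0, "CO2/N2")), duration=130.0)


@pytest.fixture
def noiseless():
    return NoiseModel(sigma=0.0, seed=0)


@pytest.fixture
def default_kinetics():
    return FilmKinetics()
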