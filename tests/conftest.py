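import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dielax as dx

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def glycine_model() -> dx.RelaxationModel:
    return dx.fixture("glycine_solution")


@pytest.fixture
def water_model() -> dx.RelaxationModel:
    return dx.fixture("water_293K")


@pytest.fixture
def tdr_band() -> dx.BandSpec:
    return dx.TDR_BAND


@pytest.fixture
def water_solvent() -> dx.SolventConditions:
    return dx.SolventConditions(temperature=293.0, viscosity=1.002e-3)


@pytest.fixture
def simple_spectrum() -> dx.PermittivitySpectrum:
    return dx.PermittivitySpectrum(
        frequency=np.array([1e9, 2e9, 3e9]),
        eps_real=np.array([70.0, 60.0, 50.0]),
        eps_imag=np.array([10.0, 20.0, 25.0]),
        band_label="TDR",
    )
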