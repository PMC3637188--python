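import cmath

import numpy as np
import pytest

from cibeam import ArrayConfig, FilterBankSpec, LinearizedModel


@pytest.fixture(scope="session")
def array():
    return ArrayConfig()  # d = 1 cm, c = 340 m/s


@pytest.fixture(scope="session")
def bank():
    return FilterBankSpec.default_8()


@pytest.fixture(scope="session")
def model():
    return LinearizedModel.from_array()


def complex_oracle(d, c, beta, tau, theta_deg, f):
    """Independent response oracle: modulus of 1 - beta*exp(-j*phi)."""
    phi = 2.0 * np.pi * f * (d * np.cos(np.deg2rad(theta_deg)) / c + tau)
    return abs(1.0 - beta * cmath.exp(-1j * phi))
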