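"""Shared fixtures: default sequence parameters and cached basis sets."""

import pytest

from gabaedit.sequence import SequenceParams
from gabaedit.simulate import make_basis


@pytest.fixture(scope="session")
def params():
    """The 7 T protocol defaults (TE 68 ms, 297.2 MHz, 2048 points)."""
    return SequenceParams()


@pytest.fixture(scope="session")
def basis_sym(params):
    """Full basis set under symmetric-1.7 editing (simulated once)."""
    return make_basis(params, "symmetric_1p7")


@pytest.fixture(scope="session")
def basis_water(params):
    """Full basis set under water-symmetric editing."""
    return make_basis(params, "water_symmetric")


@pytest.fixture(scope="session")
def small_params():
    """Reduced sampling for cheap pipeline-level tests."""
    return SequenceParams(n_points=1024, sweep_hz=3000.0)
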