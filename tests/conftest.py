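import pytest

from mnephys.cohort import default_protocol_set
from mnephys.params import MNParameters, passive_parameters
from mnephys.simulate import simulate


@pytest.fixture(scope="session")
def protocols():
    """Default protocol battery keyed by protocol id."""
    return {p.protocol_id: p for p in default_protocol_set()}


@pytest.fixture(scope="session")
def passive_cell():
    return passive_parameters(C=200.0, gL=20.0, EL=-60.0)


@pytest.fixture(scope="session")
def default_cell():
    return MNParameters()


@pytest.fixture(scope="session")
def passive_vc_fast(passive_cell, protocols):
    """Noise-free fast voltage ramp on the passive cell."""
    return simulate(passive_cell, protocols["vc_ramp_5s"], seed=None)


@pytest.fixture(scope="session")
def default_cc_ramp(default_cell, protocols):
    """Noise-free current ramp on the default (sham) cell."""
    return simulate(default_cell, protocols["cc_ramp"], seed=None)
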