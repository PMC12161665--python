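import numpy as np
import pytest

from aggpop import ThermoContext, phenol_spec, solvent_spec


@pytest.fixture(scope="session")
def ctx():
    return ThermoContext()


@pytest.fixture(scope="session")
def specs():
    solv = solvent_spec()
    return {"phenol": phenol_spec(), solv.name: solv}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
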