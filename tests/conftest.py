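import numpy as np
import pytest

from splaycpg.neuron import find_limit_cycle
from splaycpg.phase import compute_prc
from splaycpg.presets import preset_current, preset_params


@pytest.fixture(scope="session")
def snl_params():
    return preset_params("SNL")


@pytest.fixture(scope="session")
def snl_current():
    return preset_current("SNL")


@pytest.fixture(scope="session")
def snl_cycle(snl_params, snl_current):
    return find_limit_cycle(snl_params, snl_current)


@pytest.fixture(scope="session")
def snl_prc(snl_params, snl_current, snl_cycle):
    return compute_prc(snl_params, snl_current, cycle=snl_cycle, n_phases=64)


@pytest.fixture(scope="session")
def snic_params():
    return preset_params("SNIC")


@pytest.fixture(scope="session")
def snic_current():
    return preset_current("SNIC")


@pytest.fixture(scope="session")
def snic_cycle(snic_params, snic_current):
    return find_limit_cycle(snic_params, snic_current)


@pytest.fixture(scope="session")
def snic_prc(snic_params, snic_current, snic_cycle):
    return compute_prc(snic_params, snic_current, cycle=snic_cycle, n_phases=64)
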