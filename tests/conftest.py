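import pytest

from crnrpa.cholesterol import (
    cholesterol_network,
    cholesterol_subnetworks,
    reference_fixture,
)
from crnrpa.mass_action import build_ode_system, closed_form_steady_state


@pytest.fixture(scope="session")
def crn():
    return cholesterol_network()


@pytest.fixture(scope="session")
def subnets():
    return cholesterol_subnetworks()


@pytest.fixture(scope="session")
def odes(crn):
    return build_ode_system(crn)


@pytest.fixture(scope="session")
def steady_state(odes):
    return closed_form_steady_state(odes)


@pytest.fixture(scope="session")
def reference():
    return reference_fixture()
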