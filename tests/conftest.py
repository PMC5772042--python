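"""Shared fixtures.

Expensive periodic-steady-state runs of the built-in patient network are
session-scoped so the directional and conservation checks reuse them.
"""

import pytest

from coroflow.patient import default_fixture_drivers, load_patient_fixture
from coroflow.simulate import SimulationConfig, run_to_periodic
from coroflow.units import PhysicalConstants


@pytest.fixture(scope="session")
def constants():
    return PhysicalConstants()


@pytest.fixture(scope="session")
def fixture_network(constants):
    return load_patient_fixture(constants)


@pytest.fixture(scope="session")
def fixture_drivers(constants):
    return default_fixture_drivers(constants)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def baseline_waves(fixture_network, fixture_drivers, sim_config, constants):
    """Converged cycle of the unmodified patient network."""
    return run_to_periodic(fixture_network, fixture_drivers, sim_config, constants)


@pytest.fixture(scope="session")
def no_headloss_waves(fixture_network, fixture_drivers, sim_config, constants):
    """Converged cycle with the ostial head-loss elements removed."""
    return run_to_periodic(
        fixture_network.without_headloss(), fixture_drivers, sim_config, constants
    )
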