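import pytest
from hypothesis import HealthCheck, settings

import rbnxcs as rx

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def and_motif():
    return rx.motif_network("AND")


@pytest.fixture
def xor_motif():
    return rx.motif_network("XOR")


@pytest.fixture
def xor_fixed_point_task(xor_motif):
    """XOR motif with the 000 fixed point as the control target."""
    return rx.ControlTask(xor_motif, rx.Attractor(("000",)))


@pytest.fixture
def xor_cycle_task(xor_motif):
    """XOR motif with the 3-state cycle as the control target."""
    return rx.ControlTask(xor_motif, rx.Attractor(("011", "110", "101")))


@pytest.fixture
def default_params():
    return rx.XcsParams()


@pytest.fixture
def small_params():
    """A small-capacity parameter set for fast engine tests."""
    return rx.XcsParams(R=120, theta_mna=4)
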