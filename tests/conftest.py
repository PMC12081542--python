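import numpy as np
import pytest

from tblmkit import MembraneScenario, MembraneSpec, RampProtocol, \
    simulate_vi_trace


@pytest.fixture
def protocol():
    """The chip-reader ramp: 0-500 mV, 5 mV / 0.05 ms (100 V/s)."""
    return RampProtocol()


@pytest.fixture
def membrane_spec():
    return MembraneSpec()


@pytest.fixture
def piecewise_scenario():
    """The reference noise-free three-region membrane used for round-trips."""
    return MembraneScenario(
        capacitance=50e-9, g_low=0.2e-6, g_high=2e-6,
        v_break1=0.15, v_break2=0.30,
    )


@pytest.fixture
def piecewise_trace(protocol, piecewise_scenario):
    return simulate_vi_trace(protocol, piecewise_scenario)


def assert_rel(actual, expected, rtol, msg=""):
    assert expected != 0
    assert abs(actual / expected - 1.0) <= rtol, \
        f"{msg} got {actual!r}, want {expected!r} within {rtol}"


def round_1sf(x):
    """Round to one significant figure (the reference values' precision)."""
    if x == 0:
        return 0.0
    return float(f"{x:.0e}")
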