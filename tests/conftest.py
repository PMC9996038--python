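import numpy as np
import pytest

from hergfit import GatingParams, RateParams, ThermoContext


@pytest.fixture(scope="session")
def ctx() -> ThermoContext:
    return ThermoContext()  # 295.15 K


@pytest.fixture(scope="session")
def control_gating() -> GatingParams:
    """Split-channel control gating parameters (K0, z1, Ko0, z2)."""
    return GatingParams(K0=0.155, z1=1.71, Ko0=0.32, z2=0.73)


@pytest.fixture(scope="session")
def rpr_gating() -> GatingParams:
    """Split-channel gating parameters in 30 uM RPR260243."""
    return GatingParams(K0=0.023, z1=2.98, Ko0=0.513, z2=0.81)


@pytest.fixture(scope="session")
def control_rates(control_gating) -> RateParams:
    return RateParams(gating=control_gating)


@pytest.fixture(scope="session")
def voltage_grid() -> np.ndarray:
    """Activation-range test-potential grid, -60..+60 mV in 10-mV steps."""
    return np.arange(-60.0, 61.0, 10.0)
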