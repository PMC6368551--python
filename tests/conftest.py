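import numpy as np
import pytest

from brineage import TransportParams


@pytest.fixture(scope="session")
def heph_mg_params() -> TransportParams:
    """Hephaestus Mg2+ transport parameters (brine 4,720, seawater 61 mmol/kg)."""
    return TransportParams(Ds=2.4e-10, Vs=9.51e-11, C0=4720.0, Cbg=61.0)


@pytest.fixture(scope="session")
def heph_dd_params() -> TransportParams:
    """Hephaestus delta-D parameters (isotope-scaled diffusivity)."""
    return TransportParams(Ds=2.96e-10, Vs=9.51e-11, C0=-16.5, Cbg=5.1)


@pytest.fixture(scope="session")
def core_depths() -> np.ndarray:
    """3.2-m core sampled every 0.2 m."""
    return np.round(np.arange(0.0, 3.2001, 0.2), 10)
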