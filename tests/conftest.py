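import numpy as np
import pytest

from lipokin import MLVSpec


@pytest.fixture(scope="session")
def unit_biot_spec() -> MLVSpec:
    """Vesicle with Biot number exactly 1 (kC R / D = 1)."""
    return MLVSpec(radius=1e-6, diffusivity=1e-12, surface_coeff=1e-6)


@pytest.fixture(scope="session")
def tau_grid() -> np.ndarray:
    """Dimensionless times spanning early transient to near-complete leakage."""
    return np.array([0.001, 0.01, 0.1, 0.5, 1.0])
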