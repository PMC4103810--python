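import numpy as np
import pytest
from hypothesis import settings

from pipbind import AnisotropyCalibration

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def paper_calibration():
    """Assay calibration at the published endpoint anisotropies and Q."""
    return AnisotropyCalibration(r_free=0.0470, r_bound=0.1587, q_ratio=0.70)


@pytest.fixture
def titration_grid():
    """12-point log grid spanning 10 nM – 32 µM protein monomer."""
    return np.logspace(-8, -4.5, 12)


@pytest.fixture
def competition_grid():
    """16-point 2-fold serial dilution from 100 µM competitor, plus zero."""
    return np.sort(np.array([1e-4 / 2.0 ** k for k in range(15)] + [0.0]))
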