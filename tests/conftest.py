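import numpy as np
import pytest

from spermsim import SimulationConfig, solve_field
from spermsim.gradient import PM


@pytest.fixture(scope="session")
def default_field():
    """Standard field: egg 100 μm, edge 5000 μm, surface 100 pM (0.1 nM)."""
    return solve_field(100.0, 5000.0, 100.0 * PM)


@pytest.fixture
def tiny_su():
    """Small, fast sea urchin cohort config for structural tests."""
    return SimulationConfig.sea_urchin(
        start_distance=400.0, n_sperm=16, duration_frames=300, seed=42
    )


@pytest.fixture
def tiny_sf():
    return SimulationConfig.starfish(
        start_distance=400.0, n_sperm=16, duration_frames=300, seed=42
    )


def rate_se(p: float, n: int) -> float:
    """Binomial standard error of an arrival-rate estimate."""
    return np.sqrt(p * (1.0 - p) / n)
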