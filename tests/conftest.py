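import numpy as np
import pytest

from hmod.grid import GridSpec, Layer, footprint
from hmod.synth import LandscapeConfig, generate_landscape


@pytest.fixture
def grid90():
    """Small 90 m grid for hand-built layers."""
    return GridSpec(8, 8, 90.0)


@pytest.fixture
def grid300():
    return GridSpec(8, 8, 300.0)


@pytest.fixture(scope="session")
def small_bundle():
    """One 48x48 synthetic landscape shared across tests (read-only)."""
    return generate_landscape(LandscapeConfig(n_rows=48, n_cols=48, seed=7))


def make_layer(grid: GridSpec, value: float, kind: str = "H") -> Layer:
    return Layer(grid, np.full(grid.shape, value), kind=kind)
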