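"""Shared fixtures: coarse solver settings keep simulations fast while
preserving the default phantom geometry and physics."""

import numpy as np
import pytest

from thermotomo.heatsim import SolverConfig, TemperatureVolume, simulate
from thermotomo.phantom import (
    HeatSource,
    MultiSourceSpec,
    PhantomSpec,
    VoxelGridSpec,
    support_mask,
)

COARSE_SPACING = 0.0025   # m; coarsest spacing that resolves the 2.5 mm source


@pytest.fixture(scope="session")
def phantom():
    return PhantomSpec()


@pytest.fixture(scope="session")
def coarse_grid(phantom):
    return VoxelGridSpec.for_phantom(phantom, COARSE_SPACING)


@pytest.fixture(scope="session")
def coarse_support(phantom, coarse_grid):
    return support_mask(phantom, coarse_grid)


@pytest.fixture(scope="session")
def centered_source():
    return HeatSource(radial_offset=0.0, height=0.025, delta_temp=30.0)


@pytest.fixture(scope="session")
def offaxis_source():
    return HeatSource(radial_offset=0.025, height=0.025, delta_temp=30.0)


@pytest.fixture(scope="session")
def centered_volume(phantom, centered_source):
    """Centred source simulated to 30 min on the coarse grid."""
    cfg = SolverConfig(spacing=COARSE_SPACING, duration=1800.0,
                       capture_times=(1800.0,))
    return simulate(phantom, MultiSourceSpec.single(centered_source), cfg)[-1]


@pytest.fixture(scope="session")
def offaxis_volume(phantom, offaxis_source):
    cfg = SolverConfig(spacing=COARSE_SPACING, duration=1800.0,
                       capture_times=(1800.0,))
    return simulate(phantom, MultiSourceSpec.single(offaxis_source), cfg)[-1]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def gaussian_volume(grid, support, center_xyz, sigma=0.01, amp=10.0,
                    timestamp=0.0):
    """Smooth synthetic ΔT blob, zero outside support (test helper)."""
    x, y, z = grid.axes()
    cx, cy, cz = center_xyz
    d2 = ((x[:, None, None] - cx) ** 2 + (y[None, :, None] - cy) ** 2
          + (z[None, None, :] - cz) ** 2)
    vals = amp * np.exp(-d2 / (2.0 * sigma ** 2))
    vals[~support] = 0.0
    return TemperatureVolume(values=vals, grid=grid, support=support,
                             timestamp=timestamp)
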