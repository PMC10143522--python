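"""Shared fixtures.

The filter-holder flow and transport solutions are expensive (minutes of
simulated time at small explicit steps), so they are computed once per
session and shared between the holder tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from spikertd.compartment import CompartmentParams, SpikeSchedule
from spikertd.holder import (
    HolderGeometry,
    advect_diffuse,
    build_grid,
    solve_flow,
    trace_particles,
)
from spikertd.hydraulics import FluidProps

FITTED_TAUS = CompartmentParams(4.3, (4.1, 1.0))


@pytest.fixture(scope="session")
def fitted_params() -> CompartmentParams:
    """Space times that reproduce the bench RTD curves."""
    return FITTED_TAUS


@pytest.fixture(scope="session")
def holder_geom() -> HolderGeometry:
    return HolderGeometry()


@pytest.fixture(scope="session")
def fluid() -> FluidProps:
    return FluidProps()


@pytest.fixture(scope="session")
def flow64(holder_geom, fluid):
    grid = build_grid(holder_geom, 64, 64)
    return solve_flow(holder_geom, grid, fluid, 4.3e-4)


@pytest.fixture(scope="session")
def flow32(holder_geom, fluid):
    grid = build_grid(holder_geom, 32, 32)
    return solve_flow(holder_geom, grid, fluid, 4.3e-4)


@pytest.fixture(scope="session")
def transport_short_64(flow64):
    """1-min spike through the 64x64 holder, 10-min horizon."""
    return advect_diffuse(flow64, SpikeSchedule(t_spike=1.0), horizon=10.0)


@pytest.fixture(scope="session")
def transport_short_32(flow32):
    return advect_diffuse(flow32, SpikeSchedule(t_spike=1.0), horizon=10.0)


@pytest.fixture(scope="session")
def transport_long_64(flow64):
    """40-min spike; the holder saturates well before the spike ends."""
    return advect_diffuse(flow64, SpikeSchedule(t_spike=40.0), horizon=8.0)


@pytest.fixture(scope="session")
def particles(flow64):
    return trace_particles(flow64, n=5000, seed=11)
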