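"""Shared fixtures: lattice geometries and session-scoped Stokes solves.

Two geometries recur throughout the suite:

* the *lane benchmark* cell — cell edge 8 μm, post radius 3.6 μm (gap one
  tenth of the edge), used for the lane/streamline structure checks;
* the *transport* cell — cell edge 8 μm, post radius 3.2 μm (1.6 μm gap),
  wide enough for 0.3–0.5 μm particles to transit, used for ensemble runs.

Flow solves are session scoped: each geometry/tilt is solved once.
"""

import numpy as np
import pytest

from dldsim import FluidSpec, LatticeSpec, solve_unit_cell_flow


@pytest.fixture(scope="session")
def fluid():
    return FluidSpec(viscosity=1.0e-3, temperature=298.0,
                     relative_permittivity=78.5, mean_flow_speed=40.0)


@pytest.fixture(scope="session")
def benchmark_lattice():
    return LatticeSpec(cell_edge=8.0, obstacle_radius=3.6, tilt_numerator=1,
                       tilt_denominator=10, device_length=11_000.0)


@pytest.fixture(scope="session")
def lattice_tilt4():
    return LatticeSpec(cell_edge=8.0, obstacle_radius=3.6, tilt_numerator=1,
                       tilt_denominator=4, device_length=11_000.0)


@pytest.fixture(scope="session")
def transport_lattice():
    return LatticeSpec(cell_edge=8.0, obstacle_radius=3.2, tilt_numerator=1,
                       tilt_denominator=10, device_length=11_000.0)


@pytest.fixture(scope="session")
def flow_benchmark(benchmark_lattice, fluid):
    return solve_unit_cell_flow(benchmark_lattice, fluid,
                                resolution=600, solver_resolution=160)


@pytest.fixture(scope="session")
def flow_tilt4(lattice_tilt4, fluid):
    return solve_unit_cell_flow(lattice_tilt4, fluid,
                                resolution=600, solver_resolution=160)


@pytest.fixture(scope="session")
def flow_transport(transport_lattice, fluid):
    return solve_unit_cell_flow(transport_lattice, fluid,
                                resolution=600, solver_resolution=160)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
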