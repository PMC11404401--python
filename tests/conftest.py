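"""Shared fixtures: small lattices and one session-wide fluid-derived lattice."""

import numpy as np
import pytest

from polypotts.lattice_factory import fluid_voronoi_lattice
from polypotts.polylattice import PeriodicBox, build_hexagonal, build_square


@pytest.fixture(scope="session")
def square_lattice():
    return build_square(40, 40, 1.0)


@pytest.fixture(scope="session")
def hex_lattice():
    # box within 2% of tileable by area-40 hexagon cells (63 ~ 10*sqrt(40))
    return build_hexagonal(63, 64, 1.0)


@pytest.fixture(scope="session")
def fluid_lattice():
    """Reduced fluid-derived Voronoi lattice shared by the simulation tests.

    ~4800 sites of unit area in a box exactly tileable by 120 hexagons of
    area 40.  Around 120 cells the reduced system still shows the fluid
    phase's bimodal shape statistics at alpha = 1.8; much smaller systems
    order prematurely.
    """
    lattice, box = fluid_voronoi_lattice(4800, t_w_gen=3000, seed=42)
    return lattice, box


def triangular_centers(n_cols: int, n_rows: int, a: float = 1.0):
    """Perfect triangular point lattice and its periodic box (n_rows even)."""
    assert n_rows % 2 == 0
    h = a * np.sqrt(3.0) / 2.0
    pts = np.array([[(c + 0.5 * (r % 2)) * a, r * h]
                    for r in range(n_rows) for c in range(n_cols)])
    return pts, PeriodicBox(n_cols * a, n_rows * h)


@pytest.fixture
def tri_centers():
    return triangular_centers(8, 8)
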