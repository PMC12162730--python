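"""Shared fixtures.

The four closure simulations used across the suite (optimal-region design at
two mesh resolutions plus the two leaflet-area comparison designs) are
session-scoped: they dominate the runtime and every consumer reads them
read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

from trivalve.geometry import build_constructed_valve, derive_design
from trivalve.closure import simulate_closure, SolverConfig

# study-grade solver settings: 30 ramp increments, 1-thickness contact
# detection, iteration cap that the hold window tops up
STUDY_CONFIG = SolverConfig(contact_detect_factor=1.0, max_iters=600)

# default study mesh and its ~1.5x-element refinement
MESH_DEFAULT = dict(n_circ=18, n_leaflet_rows=9, n_below_rows=6)
MESH_FINE = dict(n_circ=22, n_leaflet_rows=11, n_below_rows=7)


def _run(D: float, H: float, mesh: dict):
    surface = build_constructed_valve(derive_design(D, H), **mesh)
    return simulate_closure(surface, config=STUDY_CONFIG)


@pytest.fixture(scope="session")
def closure_opt():
    """Optimal-region design (D=16, H=11) at the default study mesh."""
    return _run(16.0, 11.0, MESH_DEFAULT)


@pytest.fixture(scope="session")
def closure_opt_fine():
    """Same design with ~1.5x the elements (mesh-stability check)."""
    return _run(16.0, 11.0, MESH_FINE)


@pytest.fixture(scope="session")
def closure_case1():
    """Case I: larger leaflet area (D=16.5, H=12, LA = 311 mm^2)."""
    return _run(16.5, 12.0, MESH_DEFAULT)


@pytest.fixture(scope="session")
def closure_case2():
    """Case II: smaller leaflet area (D=15.625, H=8.25, LA = 202 mm^2)."""
    return _run(15.625, 8.25, MESH_DEFAULT)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
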