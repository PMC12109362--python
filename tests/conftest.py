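"""Shared solver fixtures.

The converged fields and sweep tables are expensive (seconds to minutes per
configuration), so they are computed once per session and shared between the
unit, trend and acceptance tests.  All sweep fixtures use the coarse
quick-turnaround profile (conduits at their minimum developed-flow lengths);
the solver-property fixtures use the full-length channel at h = D1/30.
"""

import numpy as np
import pytest

import stentflow as sf
from stentflow import sweeps


@pytest.fixture(scope="session")
def poiseuille():
    """Straight channel at scaled Re=100, h = D1/30: (field, mask, geometry)."""
    geom = sf.make_channel(30, 300)
    mask = sf.rasterize(geom, sf.GridSpec(h=1.0))
    bcs = sf.BoundaryConditions(v_inlet=0.8)
    fluid = sf.scale_reynolds(sf.FluidProperties(), bcs, geom, 100.0)
    field = sf.solve_steady(mask, fluid, bcs,
                            sf.SolverSettings(tol=1e-5, max_iter=4000))
    assert field.converged
    return field, mask, geom


@pytest.fixture(scope="session")
def fast():
    return sweeps.fast_profile()


@pytest.fixture(scope="session")
def branch_run(fast):
    """Canonical stented right-angle configuration: (row, field, mask)."""
    return sweeps.run_single(90.0, 10.0, profile=fast, return_field=True)


@pytest.fixture(scope="session")
def no_stent_sweep(fast):
    return sweeps.run_no_stent_angle_sweep(profile=fast)


@pytest.fixture(scope="session")
def angle_depth_sweep(fast):
    return sweeps.run_angle_depth_sweep(profile=fast)


@pytest.fixture(scope="session")
def diameter_sweep(fast):
    return sweeps.run_diameter_sweep(profile=fast)


@pytest.fixture(scope="session")
def bevel_pair(fast):
    return sweeps.compare_bevel(profile=fast)
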