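"""Shared fixtures: meshes and solved states reused across test modules.

Session-scoped because each solve costs a fraction of a second and many
tests interrogate the same solved state; everything is deterministic, so
sharing is safe.
"""

import numpy as np
import pytest

import ocufrac as oc

A_DEFAULT = 1.1e-3  # half-length of the 2.2 mm reference incision [m]
D_INJECTOR = 1.73e-3


@pytest.fixture(scope="session")
def coarse_params():
    """Cheap discretization for invariant/topology tests (not for accuracy)."""
    return oc.MeshParams(n_spokes=16, crack_spacing_cap_frac=1 / 8,
                         far_field_size=6e-3, outer_growth=1.7, n_blend=5)


@pytest.fixture(scope="session")
def material():
    return oc.Material.isotropic()


@pytest.fixture(scope="session")
def straight_mesh(coarse_params):
    shape = oc.IncisionShape.straight(A_DEFAULT)
    return oc.build_mesh(oc.PlateSpec(), oc.make_crack_path(shape), coarse_params)


@pytest.fixture(scope="session")
def straight_solution(straight_mesh, material):
    return oc.assemble_and_solve(straight_mesh, material, oc.LoadCase(1e6))


@pytest.fixture(scope="session")
def straight_mesh_fine():
    """Production-accuracy mesh of the straight reference incision."""
    shape = oc.IncisionShape.straight(A_DEFAULT)
    return oc.build_mesh(oc.PlateSpec(), oc.make_crack_path(shape), oc.MeshParams())


@pytest.fixture(scope="session")
def straight_solution_fine(straight_mesh_fine, material):
    return oc.assemble_and_solve(straight_mesh_fine, material, oc.LoadCase(1e6))


@pytest.fixture(scope="session")
def chevron150_mesh():
    shape = oc.IncisionShape.chevron(A_DEFAULT, 150.0)
    return oc.build_mesh(oc.PlateSpec(), oc.make_crack_path(shape), oc.MeshParams())


@pytest.fixture(scope="session")
def chevron150_solution(chevron150_mesh, material):
    return oc.assemble_and_solve(chevron150_mesh, material, oc.LoadCase(3.95e6))
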