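"""Shared fixtures: geometry, coarse meshes and solvers are built once per
session — everything here is deterministic, so sharing is safe."""

from __future__ import annotations

import numpy as np
import pytest

from tonofem import fem as F
from tonofem import geometry as G
from tonofem import meshing as M
from tonofem.contact import IndentationSolver


@pytest.fixture(scope="session")
def params() -> G.OcularGeometryParams:
    return G.OcularGeometryParams()


@pytest.fixture(scope="session")
def eye_shell(params):
    return G.build_eye_shell(params)


@pytest.fixture(scope="session")
def eye_mesh_coarse(eye_shell):
    return M.sweep_shell_mesh(eye_shell, 16, 16, 2, order=1)


@pytest.fixture(scope="session")
def eye_mesh_medium(eye_shell):
    """Coarse-but-usable trilinear mesh for contact property tests."""
    return M.sweep_shell_mesh(eye_shell, 32, 28, 2, order=1)


@pytest.fixture(scope="session")
def materials():
    return F.default_materials()


@pytest.fixture(scope="session")
def eye_solver_medium(eye_mesh_medium, materials):
    return IndentationSolver(eye_mesh_medium, materials)


@pytest.fixture(scope="session")
def eye_solver_quadratic(eye_shell, materials):
    """Serendipity-quadratic mesh: resolution-sensitive force properties
    need the bending-accurate discretisation."""
    mesh = M.sweep_shell_mesh(eye_shell, 24, 20, 2, order=2)
    return IndentationSolver(mesh, materials)


@pytest.fixture(scope="session")
def sphere_shell():
    return G.make_sphere_fixture(11.2, 0.317)


@pytest.fixture(scope="session")
def sphere_mesh_coarse(sphere_shell):
    return M.sweep_shell_mesh(sphere_shell, 12, 12, 2, order=1)


@pytest.fixture(scope="session")
def one_material():
    m = F.IsotropicMaterial(2.0, 0.4)
    return {"cornea": m, "sclera": m, "junction": m}


def single_hex_mesh(coords: np.ndarray, order: int = 1) -> M.ShellMesh:
    """A one-element mesh around explicit corner (and midside) nodes."""
    nen = 8 if order == 1 else 20
    assert coords.shape == (nen, 3)
    return M.ShellMesh(
        nodes=np.asarray(coords, dtype=float),
        elems=np.arange(nen).reshape(1, -1),
        order=order,
        region_id=np.zeros(1, dtype=np.int32),
        region_names={0: "block"},
        face_sets={},
        resolution=(1, 1, 1),
        meta={},
    )
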