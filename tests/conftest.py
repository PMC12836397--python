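"""Shared geometry fixtures: spheres, flat grids, folded sheets, cohorts."""

import numpy as np
import pytest

import intrinsic_thickness as it


@pytest.fixture(scope="session")
def icosphere50():
    """Radius-50 mm icosphere, subdivision 4 (2562 vertices)."""
    return it.make_icosphere(50.0, 4)


@pytest.fixture(scope="session")
def flat_grid():
    """Flat 20 x 20 unit-spacing triangulated grid in the z = 0 plane."""
    spec = it.SheetSpec(extent=(20.0, 20.0), spacing=1.0, amplitude=0.0)
    mesh, curv, sulc = it.make_folded_sheet(spec)
    return mesh, curv, sulc


@pytest.fixture(scope="session")
def folded_sheet():
    """Default folded sheet with analytic curvature ground truth."""
    mesh, curv, sulc = it.make_folded_sheet(it.SheetSpec())
    return mesh, curv, sulc


@pytest.fixture(scope="session")
def small_cohort():
    """Five-subject default cohort (seed 11) for statistics tests."""
    return it.make_cohort(n_subjects=5, seed=11)


def make_cylinder_patch(radius=10.0, length=40.0, n_circ=120, n_len=41,
                        arc=np.pi):
    """Open cylindrical patch of given radius with outward normals."""
    thetas = np.linspace(0, arc, n_circ)
    zs = np.linspace(0, length, n_len)
    T, Z = np.meshgrid(thetas, zs, indexing="ij")
    verts = np.column_stack([
        radius * np.cos(T).ravel(), radius * np.sin(T).ravel(), Z.ravel()
    ])
    ii, jj = np.meshgrid(np.arange(n_circ - 1), np.arange(n_len - 1),
                         indexing="ij")
    v00 = (ii * n_len + jj).ravel()
    v10 = ((ii + 1) * n_len + jj).ravel()
    v01 = (ii * n_len + jj + 1).ravel()
    v11 = ((ii + 1) * n_len + jj + 1).ravel()
    tris = np.concatenate([
        np.column_stack([v00, v11, v10]), np.column_stack([v00, v01, v11])
    ])
    mesh = it.build_mesh(verts, tris)
    n = mesh.vertex_normals[mesh.n_vertices // 2]
    p = verts[mesh.n_vertices // 2].copy()
    p[2] = 0
    if np.dot(n, p) < 0:
        mesh = it.build_mesh(verts, tris[:, ::-1])
    return mesh


@pytest.fixture(scope="session")
def cylinder_patch():
    return make_cylinder_patch()
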