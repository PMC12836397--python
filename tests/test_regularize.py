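"""Barycentric resampling and geodesic-Gaussian smoothing."""

import numpy as np
import pytest

import intrinsic_thickness as it
from intrinsic_thickness.io_formats import VertexMetric
from intrinsic_thickness.regularize import (SphericalCorrespondence,
                                            resample_metric, resample_surface,
                                            smooth_metric, smooth_surface)


@pytest.fixture(scope="module")
def nested_spheres():
    """Anatomical sphere (subdiv 4, r=50) with its own unit sphere, and a
    coarser target unit sphere (subdiv 3)."""
    native_anat = it.make_icosphere(50.0, 4)
    native_sphere = it.make_icosphere(1.0, 4)
    target_sphere = it.make_icosphere(1.0, 3)
    return native_anat, native_sphere, target_sphere


class TestResampling:
    def test_identity_resample(self, nested_spheres):
        native_anat, native_sphere, _ = nested_spheres
        corr = SphericalCorrespondence(native_sphere, native_sphere)
        out = resample_surface(native_anat, corr)
        assert np.allclose(out.vertices, native_anat.vertices, atol=1e-9)

    def test_linear_field_exact(self, nested_spheres):
        """A field linear in sphere position is interpolated exactly."""
        _, native_sphere, target_sphere = nested_spheres
        corr = SphericalCorrespondence(native_sphere, target_sphere)
        coeff = np.array([0.3, -1.2, 0.7])
        native_vals = native_sphere.vertices @ coeff
        out = resample_metric(VertexMetric(native_vals), corr)
        tri_idx, w = corr.mapping
        # exact within the containing plane triangle: compare to the
        # barycentric combination of the *native* positions
        pts = native_sphere.vertices[native_sphere.triangles[tri_idx]]
        expected = np.einsum("ij,ijk->ik", w, pts) @ coeff
        assert np.allclose(out.values, expected, atol=1e-12)

    def test_downsampled_sphere_radius_preserved(self, nested_spheres):
        native_anat, native_sphere, target_sphere = nested_spheres
        corr = SphericalCorrespondence(native_sphere, target_sphere)
        out = resample_surface(native_anat, corr)
        radii = np.linalg.norm(out.vertices, axis=1)
        assert out.n_vertices == target_sphere.n_vertices
        assert (np.abs(radii / 50.0 - 1) < 0.005).all()

    def test_mapping_matches_bruteforce_oracle(self, nested_spheres):
        """Containing triangles agree with an exhaustive all-triangles search."""
        _, native_sphere, target_sphere = nested_spheres
        corr = SphericalCorrespondence(native_sphere, target_sphere)
        tri_idx, w = corr.mapping
        tris = corr.native_sphere.triangles
        pts = corr.native_sphere.vertices
        rng = np.random.default_rng(0)
        for i in rng.choice(target_sphere.n_vertices, 25, replace=False):
            q = corr.target_sphere.vertices[i]
            best, best_min = None, -np.inf
            for t in range(len(tris)):
                M = pts[tris[t]].T
                try:
                    b = np.linalg.solve(M, q)
                except np.linalg.LinAlgError:
                    continue
                if b.sum() <= 0:
                    continue
                b = b / b.sum()
                if b.min() > best_min:
                    best, best_min = t, b.min()
            bary = np.linalg.solve(pts[tris[tri_idx[i]]].T, q)
            bary /= bary.sum()
            assert best_min > -1e-10
            # agreement up to ties on shared edges
            assert tri_idx[i] == best or bary.min() < 1e-8

    def test_constant_metric_preserved(self, nested_spheres):
        _, native_sphere, target_sphere = nested_spheres
        corr = SphericalCorrespondence(native_sphere, target_sphere)
        out = resample_metric(VertexMetric(np.full(native_sphere.n_vertices, 3.3)), corr)
        assert np.allclose(out.values, 3.3, atol=1e-12)

    def test_output_within_input_range(self, nested_spheres):
        _, native_sphere, target_sphere = nested_spheres
        corr = SphericalCorrespondence(native_sphere, target_sphere)
        rng = np.random.default_rng(1)
        vals = rng.uniform(1.0, 4.0, native_sphere.n_vertices)
        out = resample_metric(VertexMetric(vals), corr)
        assert out.values.min() >= vals.min() - 1e-12
        assert out.values.max() <= vals.max() + 1e-12

    def test_conservative_mask_resampling(self, nested_spheres):
        _, native_sphere, target_sphere = nested_spheres
        corr = SphericalCorrespondence(native_sphere, target_sphere)
        mask = np.ones(native_sphere.n_vertices, bool)
        mask[:30] = False
        out = resample_metric(VertexMetric(np.ones(native_sphere.n_vertices), mask), corr)
        tri_idx, w = corr.mapping
        corners = corr.native_sphere.triangles[tri_idx]
        touches_masked = ((w > 1e-12) & ~mask[corners]).any(axis=1)
        assert (~out.mask == touches_masked).all()


class TestSurfaceSmoothing:
    def test_fwhm_zero_is_identity(self, folded_sheet):
        mesh, _, _ = folded_sheet
        out = smooth_surface(mesh, 0.0)
        assert out is mesh

    def test_negative_fwhm_rejected(self, folded_sheet):
        mesh, _, _ = folded_sheet
        with pytest.raises(ValueError):
            smooth_surface(mesh, -1.0)

    def test_flat_sheet_unchanged(self, flat_grid):
        mesh, _, _ = flat_grid
        out = smooth_surface(mesh, 3.0)
        interior = ~mesh.is_boundary_vertex
        # z stays 0; in-plane coordinates may shift slightly near boundary
        assert np.abs(out.vertices[interior, 2]).max() < 1e-12

    def test_sphere_shrinkage_small(self):
        mesh = it.make_icosphere(50.0, 3)
        out = smooth_surface(mesh, 2.14)
        r0 = np.linalg.norm(mesh.vertices, axis=1).mean()
        r1 = np.linalg.norm(out.vertices, axis=1).mean()
        assert abs(r1 - r0) / r0 < 0.001


class TestMetricSmoothing:
    def test_constant_preserved_exactly(self, folded_sheet):
        mesh, curv, _ = folded_sheet
        metric = VertexMetric(np.full(mesh.n_vertices, 2.5), curv.mask.copy())
        out = smooth_metric(metric, mesh, 4.0)
        assert np.allclose(out.values[out.mask], 2.5, atol=1e-12)

    def test_extremal_bounds(self, folded_sheet):
        mesh, curv, _ = folded_sheet
        rng = np.random.default_rng(2)
        vals = rng.uniform(1.0, 4.0, mesh.n_vertices)
        out = smooth_metric(VertexMetric(vals, curv.mask.copy()), mesh, 5.0)
        assert out.values[out.mask].min() >= vals.min() - 1e-12
        assert out.values[out.mask].max() <= vals.max() + 1e-12

    def test_impulse_decays_monotonically(self, flat_grid):
        mesh, curv, _ = flat_grid
        center = mesh.n_vertices // 2
        vals = np.zeros(mesh.n_vertices)
        vals[center] = 1.0
        out = smooth_metric(VertexMetric(vals), mesh, 4.0)
        d = np.linalg.norm(mesh.vertices - mesh.vertices[center], axis=1)
        order = np.argsort(d)
        resp = out.values[order]
        # binned by distance, response decreases
        bins = np.floor(d[order]).astype(int)
        means = [resp[bins == b].mean() for b in range(4)]
        assert all(means[i] > means[i + 1] for i in range(3))

    def test_linearity(self, folded_sheet):
        mesh, curv, _ = folded_sheet
        rng = np.random.default_rng(3)
        x = rng.normal(size=mesh.n_vertices)
        y = rng.normal(size=mesh.n_vertices)
        a, b = 1.7, -0.4
        sx = smooth_metric(VertexMetric(x, curv.mask.copy()), mesh, 5.0)
        sy = smooth_metric(VertexMetric(y, curv.mask.copy()), mesh, 5.0)
        sxy = smooth_metric(VertexMetric(a * x + b * y, curv.mask.copy()), mesh, 5.0)
        assert np.allclose(sxy.values[sxy.mask],
                           a * sx.values[sxy.mask] + b * sy.values[sxy.mask],
                           atol=1e-10)

    def test_noise_variance_strictly_decreases(self, folded_sheet):
        mesh, curv, _ = folded_sheet
        rng = np.random.default_rng(4)
        m = VertexMetric(rng.normal(size=mesh.n_vertices), curv.mask.copy())
        v0 = m.values[m.mask].var()
        s1 = smooth_metric(m, mesh, 4.0)
        v1 = s1.values[s1.mask].var()
        s2 = smooth_metric(s1, mesh, 4.0)
        v2 = s2.values[s2.mask].var()
        assert v0 > v1 > v2

    def test_masked_vertices_never_contribute(self, flat_grid):
        mesh, _, _ = flat_grid
        mask = np.ones(mesh.n_vertices, bool)
        poisoned = mesh.n_vertices // 2
        mask[poisoned] = False
        vals = np.zeros(mesh.n_vertices)
        vals[poisoned] = 1e6
        out = smooth_metric(VertexMetric(vals, mask), mesh, 4.0)
        assert np.abs(out.values[out.mask]).max() == 0.0

    def test_fwhm_zero_identity(self, folded_sheet):
        mesh, curv, _ = folded_sheet
        vals = np.arange(mesh.n_vertices, dtype=float)
        out = smooth_metric(VertexMetric(vals, curv.mask.copy()), mesh, 0.0)
        assert (out.values == vals).all()


def test_resample_round_trip_bounded(nested_spheres):
    """A -> B -> A returns within the field's within-triangle nonlinearity."""
    _, native_sphere, target_sphere = nested_spheres
    down = SphericalCorrespondence(native_sphere, target_sphere)
    up = SphericalCorrespondence(target_sphere, native_sphere)
    vals = np.cos(3 * native_sphere.vertices[:, 0]) + native_sphere.vertices[:, 1]
    m0 = VertexMetric(vals)
    back = resample_metric(resample_metric(m0, down), up)
    # coarse sphere edge length ~ 0.25 -> quadratic field error ~ O(h^2)
    assert np.abs(back.values - vals).max() < 0.08
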