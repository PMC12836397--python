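"""Global and local folding compensation of thickness."""

import numpy as np
import pytest

import intrinsic_thickness as it
from intrinsic_thickness.compensate import (FLAG_IDENTITY, CompensationParams,
                                            build_local_design, fit_local,
                                            patch_weights)
from intrinsic_thickness.io_formats import VertexMetric
from intrinsic_thickness.mesh import geodesic_neighborhood


class TestGlobalCompensation:
    def test_exact_linear_model(self, folded_sheet):
        mesh, curv, _ = folded_sheet
        H = it.mean_curvature(mesh)
        t = VertexMetric(2.5 + 0.8 * H.values, H.mask)
        tcorr, fit = it.global_linear_compensation(t, H)
        assert fit.slope == pytest.approx(0.8, abs=1e-9)
        assert np.abs(tcorr.masked_values - 2.5).max() < 1e-9

    def test_constant_thickness_zero_slope(self, folded_sheet):
        mesh, curv, _ = folded_sheet
        H = it.mean_curvature(mesh)
        t = VertexMetric(np.full(mesh.n_vertices, 3.0), H.mask)
        tcorr, fit = it.global_linear_compensation(t, H)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tcorr.masked_values, 3.0)

    def test_residual_orthogonality(self, folded_sheet):
        """corr(tcorr, H) vanishes for arbitrary input (OLS property)."""
        mesh, curv, _ = folded_sheet
        H = it.mean_curvature(mesh)
        rng = np.random.default_rng(5)
        t = VertexMetric(2.5 + 1.2 * H.values + rng.normal(0, 0.3, mesh.n_vertices),
                         H.mask)
        tcorr, _ = it.global_linear_compensation(t, H)
        m = tcorr.mask
        r = np.corrcoef(tcorr.values[m], H.values[m])[0, 1]
        assert abs(r) < 1e-10

    def test_constant_regressor_rejected(self):
        t = VertexMetric([1.0, 2.0, 3.0])
        H = VertexMetric([0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="degenerate"):
            it.global_linear_compensation(t, H)


class TestLocalDesign:
    def _patch(self, folded_sheet, center=1500, fwhm=6.0):
        mesh, curv, _ = folded_sheet
        p = CompensationParams(patch_fwhm=fwhm)
        nb = geodesic_neighborhood(mesh, center, p.patch_radius)
        w = patch_weights(nb.distances, p.patch_sigma,
                          mesh.vertex_barycentric_area[nb.vertices])
        return curv, nb, w

    def test_weighted_means_are_zero(self, folded_sheet):
        _, curv, _ = folded_sheet
        curv, nb, w = self._patch(folded_sheet)
        X, F = build_local_design(curv, nb, w)
        wn = w / w.sum()
        assert np.abs(wn @ X).max() < 1e-10

    def test_constant_predictor_gives_zero_columns(self, flat_grid):
        mesh, curv, _ = flat_grid
        disc = it.compute_all(mesh)
        nb = geodesic_neighborhood(mesh, mesh.n_vertices // 2, 5.0)
        w = patch_weights(nb.distances, 2.0)
        X, _ = build_local_design(disc, nb, w)
        assert np.abs(X).max() < 1e-10

    def test_matches_independent_summation_oracle(self, folded_sheet):
        """Demeaning equals loop-based weighted means computed separately."""
        curv, nb, w = self._patch(folded_sheet, center=900)
        X, F = build_local_design(curv, nb, w)
        P = curv.predictor_matrix()[nb.vertices]
        raw = np.column_stack([P, P**2])
        # independent accumulation: plain Python loop
        means = np.zeros(10)
        for row, wi in zip(raw, w):
            means += wi * row
        means /= w.sum()
        assert np.allclose(X, raw - means, atol=1e-12)
        center_pos = list(nb.vertices).index(nb.center)
        assert np.allclose(F, raw[center_pos] - means, atol=1e-12)


class TestFitLocal:
    def test_constant_thickness(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 10))
        w = rng.uniform(0.1, 1.0, 50)
        X -= (w / w.sum()) @ X
        beta = fit_local(np.full(50, 3.1), X, w)
        assert beta[0] == pytest.approx(3.1, abs=1e-12)
        assert np.abs(beta[1:]).max() < 1e-9

    def test_exact_linear_model_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 10))
        w = rng.uniform(0.1, 1.0, 80)
        X -= (w / w.sum()) @ X
        t = 2.5 + 1.5 * X[:, 0] + 1.0 * X[:, 1]
        beta = fit_local(t, X, w, ridge_eps=0.0)
        assert beta[0] == pytest.approx(2.5, abs=1e-8)
        assert beta[1] == pytest.approx(1.5, abs=1e-8)
        assert beta[2] == pytest.approx(1.0, abs=1e-8)
        assert np.abs(beta[3:]).max() < 1e-8

    def test_matches_bruteforce_normal_equations(self):
        """WLS equals explicit sum_j w x_i x_j accumulation, 100 random patches."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = rng.integers(40, 80)
            X = rng.normal(size=(n, 10))
            w = rng.uniform(0.05, 1.0, n)
            X -= (w / w.sum()) @ X
            t = rng.normal(2.5, 0.5, n)
            eps = 1e-4
            beta = fit_local(t, X, w, ridge_eps=eps)
            # brute force: explicit elementwise sums
            A = np.zeros((10, 10))
            b = np.zeros(10)
            t0 = float((w / w.sum()) @ t)
            for i in range(10):
                for j in range(10):
                    A[i, j] = float(np.sum(w * X[:, i] * X[:, j]))
                b[i] = float(np.sum(w * X[:, i] * (t - t0)))
            lam = eps * A.diagonal().max()
            oracle = np.linalg.solve(A + lam * np.eye(10), b)
            assert np.allclose(beta[1:], oracle, atol=1e-8)

    def test_too_few_positive_weights_rejected(self):
        X = np.zeros((12, 10))
        w = np.zeros(12)
        w[:5] = 1.0
        with pytest.raises(ValueError, match="positive"):
            fit_local(np.ones(12), X, w)


class TestCompensateThickness:
    def test_flat_region_identity(self, flat_grid):
        mesh, _, _ = flat_grid
        disc = it.compute_all(mesh)
        rng = np.random.default_rng(3)
        t = VertexMetric(2.5 + rng.normal(0, 0.1, mesh.n_vertices), disc.mask.copy())
        tcorr, fit = it.compensate_thickness(mesh, t, disc, CompensationParams())
        m = tcorr.mask
        assert np.abs(tcorr.values[m] - t.values[m]).max() < 1e-9

    def test_exact_model_recovery(self, folded_sheet):
        """T linear in the true curvatures: compensation returns the constant."""
        mesh, analytic, _ = folded_sheet
        t = VertexMetric(2.5 + 1.5 * analytic.k1.values + 1.0 * analytic.k2.values,
                         analytic.mask.copy())
        tcorr, fit = it.compensate_thickness(mesh, t, analytic, CompensationParams())
        m = tcorr.mask
        rmse_in = np.sqrt(np.mean((t.values[m] - 2.5) ** 2))
        rmse_out = np.sqrt(np.mean((tcorr.values[m] - 2.5) ** 2))
        assert rmse_out < rmse_in / 50

    def test_deterministic_and_order_independent(self, flat_grid):
        """Identical inputs give bit-identical outputs on repeated runs."""
        mesh, _, _ = flat_grid
        disc = it.compute_all(mesh)
        rng = np.random.default_rng(4)
        t = VertexMetric(2.5 + rng.normal(0, 0.1, mesh.n_vertices), disc.mask.copy())
        out1, fit1 = it.compensate_thickness(mesh, t, disc, CompensationParams())
        out2, fit2 = it.compensate_thickness(mesh, t, disc, CompensationParams())
        assert (out1.values == out2.values).all()
        assert (fit1.betas == fit2.betas).all()

    def test_small_patch_falls_back_to_identity(self):
        """A mesh too small for the minimum patch count flags and passes through."""
        spec = it.SheetSpec(extent=(20.0, 20.0), spacing=2.0, amplitude=0.0, margin=1)
        mesh, curv, _ = it.make_folded_sheet(spec)
        disc = it.compute_all(mesh)
        t = VertexMetric(np.full(mesh.n_vertices, 2.5), disc.mask.copy())
        params = CompensationParams(patch_fwhm=1.0, min_patch_vertices=200)
        tcorr, fit = it.compensate_thickness(mesh, t, disc, params)
        m = tcorr.mask
        assert (fit.flags[m] == FLAG_IDENTITY).all()
        assert (tcorr.values[m] == t.values[m]).all()

    def test_beta0_is_patch_weighted_mean(self, folded_sheet):
        mesh, analytic, _ = folded_sheet
        rng = np.random.default_rng(6)
        t = VertexMetric(2.5 + rng.normal(0, 0.05, mesh.n_vertices),
                         analytic.mask.copy())
        params = CompensationParams()
        tcorr, fit = it.compensate_thickness(mesh, t, analytic, params)
        c = int(np.flatnonzero(tcorr.mask)[40])
        nb = geodesic_neighborhood(mesh, c, params.patch_radius)
        keep = tcorr.mask[nb.vertices] | ~tcorr.mask[nb.vertices]
        inm = t.mask[nb.vertices]
        J = nb.vertices[inm]
        w = patch_weights(nb.distances[inm], params.patch_sigma,
                          mesh.vertex_barycentric_area[J])
        expected = float((w / w.sum()) @ t.values[J])
        assert fit.betas[c, 0] == pytest.approx(expected, abs=1e-10)

    def test_approximate_idempotence(self, folded_sheet):
        """Second-pass changes are a small fraction of first-pass changes."""
        mesh, analytic, _ = folded_sheet
        rng = np.random.default_rng(7)
        t = VertexMetric(
            2.5 + 1.5 * analytic.k1.values + 1.0 * analytic.k2.values
            + rng.normal(0, 0.05, mesh.n_vertices),
            analytic.mask.copy(),
        )
        disc = it.compute_all(mesh)
        params = CompensationParams()
        t1, _ = it.compensate_thickness(mesh, t, disc, params)
        t2, _ = it.compensate_thickness(mesh, t1, disc, params)
        m = t2.mask
        change1 = np.sqrt(np.mean((t1.values[m] - t.values[m]) ** 2))
        change2 = np.sqrt(np.mean((t2.values[m] - t1.values[m]) ** 2))
        assert change2 < 0.10 * change1

    def test_local_linear_H_reproduces_global(self, folded_sheet):
        """With whole-mask patches and an H-only design, MR reduces to SR."""
        mesh, curv, _ = folded_sheet
        H = it.mean_curvature(mesh)
        rng = np.random.default_rng(8)
        t = VertexMetric(2.5 + 0.9 * H.values + rng.normal(0, 0.02, mesh.n_vertices),
                         H.mask)
        sr, fit_sr = it.global_linear_compensation(t, H)
        # emulate MR restricted to a linear H design spanning the whole mask
        m = t.mask & H.mask
        h = H.values[m]
        X = (h - h.mean())[:, None]
        w = np.ones(m.sum())
        beta = fit_local(t.values[m], X, w, ridge_eps=0.0)
        tcorr_h = t.values[m] - beta[1] * H.values[m]
        # equal up to the (intercept) constant
        diff = tcorr_h - sr.values[m]
        assert np.abs(diff - diff.mean()).max() < 1e-9


def test_pipeline_runs_and_reduces_folding(small_cohort):
    s = small_cohort.subjects[0]
    tcorr, fit, curv = it.compensate_pipeline(s.mesh, s.thickness,
                                              CompensationParams())
    m = tcorr.mask
    sd_in = s.thickness.values[m].std()
    sd_out = tcorr.values[m].std()
    assert sd_out < sd_in
    assert fit.n_fallback == 0
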