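"""Folding compensation of cortical thickness.

Measured cortical thickness covaries with folding: gyral crowns are
consistently thicker than sulcal fundi.  Two estimators of what thickness
would have been in the absence of folding are provided:

* **Global linear (single regression, SR).**  One ordinary least-squares fit
  of thickness ``t`` on mean curvature ``H`` over the whole analysis region:
  ``t = H*k + b``, compensated as ``tcorr = t - H*k`` (the intercept stays in
  the map).  A baseline; it underfits because the folding -> thickness
  relationship varies regionally.

* **Local nonlinear (multiple regression, MR).**  At every vertex, a weighted
  least-squares fit of thickness on the five folding predictors
  (k1, k2, K, SI, C) and their squares over a geodesic patch, with Gaussian
  weights of a given FWHM centered at the vertex:

      T = b0 + b1*X1 + ... + b5*X5 + b6*X1^2 + ... + b10*X5^2

  Predictors and their squares are demeaned with the patch weights, so b0 is
  the local weighted-mean thickness.  The compensated value is

      Tcorr = T - sum(b_1..5 * F) - sum(b_6..10 * F^2)

  where F holds the center vertex's (smoothed) curvature values themselves.
  Because the fitted columns are demeaned, the local intercept b0 — the
  patch-weighted mean thickness — stays in the map, while both the
  within-patch deviation and the patch-mean part of the folding-predicted
  thickness are removed.  (Subtracting the *demeaned* center row instead
  would return the patch-mean thickness at an exact fit, leaving the
  patch-scale folding signal in place.)

Near-planar patches (all predictors ~constant) are handled by a relative
ridge on the normal equations; if a fit is still deficient the quadratic
columns are dropped, and as a last resort ``Tcorr = T`` (the correct limit
where folding explains nothing), with the vertex flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .curvature import CurvatureSet, compute_all
from .io_formats import VertexMetric
from .mesh import TriangleMesh, GeodesicNeighborhood, geodesic_neighborhood, geodesic_neighborhoods
from .regularize import FWHM_TO_SIGMA, TRUNCATION_SIGMAS, smooth_surface

logger = logging.getLogger(__name__)

__all__ = [
    "GlobalFit",
    "LocalFit",
    "CompensationParams",
    "global_linear_compensation",
    "build_local_design",
    "fit_local",
    "compensate_thickness",
    "compensate_pipeline",
]

N_PREDICTORS = 5
N_COEFFS = 11  # intercept + 5 linear + 5 quadratic

# fit-status flags in LocalFit.flags
FLAG_OK = 0
FLAG_EXPANDED = 1  # patch radius expanded 1.5x to reach the minimum count
FLAG_LINEAR_ONLY = 2  # quadratic columns dropped
FLAG_IDENTITY = 3  # irrecoverable: Tcorr = T


@dataclass(frozen=True)
class GlobalFit:
    """Whole-region OLS of thickness on mean curvature: t = H*k + b."""

    slope: float  # mm^2 (mm per mm^-1)
    intercept: float  # mm
    n: int


@dataclass
class LocalFit:
    """Per-vertex local regression results.

    ``betas`` is (n_vertices, 11): intercept, 5 linear, 5 quadratic
    coefficients.  ``effective_n`` is the sum of normalized patch weights'
    inverse participation (kernel-weighted sample size); ``flags`` records
    the fallback route taken at each vertex.
    """

    betas: np.ndarray
    effective_n: np.ndarray
    flags: np.ndarray

    @property
    def n_fallback(self) -> int:
        return int((self.flags == FLAG_IDENTITY).sum())


@dataclass(frozen=True)
class CompensationParams:
    """The three FWHM free parameters plus numerical-stability settings.

    Defaults are the reference optimized values: 2.14 mm (surface
    smoothing), 2.52 mm (curvature smoothing), 6 mm (regression patch).
    """

    surface_fwhm: float = 2.14
    metric_fwhm: float = 2.52
    patch_fwhm: float = 6.0
    truncation: float = TRUNCATION_SIGMAS
    ridge_eps: float = 1e-4  # relative to the strongest design column
    min_patch_vertices: int = 33  # 3x the 11 regression parameters

    def __post_init__(self):
        if min(self.surface_fwhm, self.metric_fwhm, self.patch_fwhm) < 0:
            raise ValueError("FWHM parameters must be nonnegative")

    @property
    def patch_sigma(self) -> float:
        return self.patch_fwhm * FWHM_TO_SIGMA

    @property
    def patch_radius(self) -> float:
        return self.truncation * self.patch_sigma


# ------------------------------------------------------------- global (SR)

def global_linear_compensation(thickness: VertexMetric, H: VertexMetric,
                               mask=None):
    """Single-regression folding compensation: ``tcorr = t - H*k``.

    Fits ``t = H*k + b`` by OLS over in-mask vertices and removes the
    H-proportional part, keeping the intercept, so the compensated map stays
    on the thickness scale.  Returns ``(tcorr, GlobalFit)``.
    """
    m = thickness.mask & H.mask
    if mask is not None:
        m = m & np.asarray(mask, bool)
    t = thickness.values[m]
    h = H.values[m]
    if len(t) < 2:
        raise ValueError("need at least 2 in-mask vertices")
    hvar = h.var()
    if hvar == 0:
        raise ValueError("degenerate regressor: H is constant in the mask")
    k = ((h - h.mean()) * (t - t.mean())).sum() / ((h - h.mean()) ** 2).sum()
    b = t.mean() - k * h.mean()
    tcorr = thickness.values - H.values * k
    out = VertexMetric(np.where(m, tcorr, thickness.values), m, name="corrThickness")
    return out, GlobalFit(slope=float(k), intercept=float(b), n=int(m.sum()))


# -------------------------------------------------------------- local (MR)

def patch_weights(distances: np.ndarray, sigma: float,
                  areas: np.ndarray | None = None) -> np.ndarray:
    """Gaussian-in-geodesic-distance patch weights, area-weighted."""
    w = np.exp(-0.5 * (distances / sigma) ** 2)
    if areas is not None:
        w = w * areas
    return w


def build_local_design(curvatures: CurvatureSet,
                       neighborhood: GeodesicNeighborhood,
                       weights: np.ndarray):
    """Demeaned 10-column design for one patch.

    Columns 0..4 are the raw predictors (k1, k2, K, SI, C) minus their
    weighted patch means; columns 5..9 are the raw squares minus the
    weighted patch means of the squares.  Returns ``(X, center_row)`` where
    ``center_row`` is the design row of the patch center.
    """
    P = curvatures.predictor_matrix()[neighborhood.vertices]
    return _demeaned_design(P, weights, int(np.flatnonzero(
        neighborhood.vertices == neighborhood.center)[0]))


def _demeaned_design(P: np.ndarray, w: np.ndarray, center_pos: int):
    wn = w / w.sum()
    raw = np.concatenate([P, P**2], axis=1)
    mu = wn @ raw
    X = raw - mu
    return X, X[center_pos]


def _wls_solve(X: np.ndarray, w: np.ndarray, t: np.ndarray, ridge_eps: float):
    """Weighted LS of t on demeaned design X with relative ridge.

    Returns (beta0, beta[10], ok).  beta0 is the weighted mean of t (exact,
    because the columns are demeaned).  The ridge adds ``ridge_eps`` times
    the LARGEST column's weighted sum of squares to every diagonal entry:
    columns whose within-patch variance is below ~ridge_eps of the
    strongest column get coefficients shrunk toward 0.  This matters
    because the compensation subtracts beta times the RAW center values —
    a locally near-constant predictor (e.g. SI ~ +1 across a gyral crown
    patch) carries no usable variance but a raw value of order 1, so an
    unshrunk noise-driven coefficient would inject large errors.
    All-zero columns get coefficient exactly 0.
    """
    wn = w / w.sum()
    beta0 = float(wn @ t)
    Xw = X * w[:, None]
    A = X.T @ Xw
    b = Xw.T @ (t - beta0)
    colss = np.diag(A).copy()
    zero = colss <= 0
    lam = ridge_eps * max(float(colss.max(initial=0.0)), 1e-300)
    A = A.copy()
    np.fill_diagonal(A, colss + lam)
    A[zero, :] = 0.0
    A[:, zero] = 0.0
    A[zero, zero] = 1.0
    b[zero] = 0.0
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return beta0, np.zeros(X.shape[1]), False
    if not np.isfinite(beta).all():
        return beta0, np.zeros(X.shape[1]), False
    return beta0, beta, True


def fit_local(thickness: np.ndarray, design: np.ndarray, weights: np.ndarray,
              ridge_eps: float = 1e-8) -> np.ndarray:
    """Solve one patch's weighted least squares; returns the 11 coefficients.

    ``thickness`` holds the raw patch thickness values, ``design`` the
    demeaned 10-column matrix, ``weights`` the nonnegative patch weights.
    """
    if (np.asarray(weights) < 0).any():
        raise ValueError("weights must be nonnegative")
    if int((np.asarray(weights) > 0).sum()) < N_COEFFS:
        raise ValueError(f"need at least {N_COEFFS} strictly positive weights")
    beta0, beta, ok = _wls_solve(np.asarray(design, float), np.asarray(weights, float),
                                 np.asarray(thickness, float), ridge_eps)
    if not ok:
        raise np.linalg.LinAlgError("rank-deficient patch even after ridge")
    return np.concatenate([[beta0], beta])


def compensate_thickness(mesh: TriangleMesh, thickness: VertexMetric,
                         curvatures: CurvatureSet,
                         params: CompensationParams = CompensationParams(),
                         mask=None):
    """Local multiple-regression folding compensation at every in-mask vertex.

    For each vertex: gather the geodesic patch (Gaussian weights of
    ``params.patch_fwhm``), build the demeaned linear+quadratic design, solve
    the weighted least squares, and subtract the folding-predicted part:
    ``Tcorr = T - F . beta[1:6] - F^2 . beta[6:11]`` with F the raw predictor
    values at the center.  Patches with fewer than
    ``params.min_patch_vertices`` in-mask members expand their radius 1.5x
    once, then fall back to ``Tcorr = T`` (flagged).  Vertices are processed
    independently; results do not depend on execution order.

    Returns ``(Tcorr, LocalFit)``.
    """
    n = mesh.n_vertices
    m = thickness.mask & curvatures.mask
    if mask is not None:
        m = m & np.asarray(mask, bool)
    sigma = params.patch_sigma
    radius = params.patch_radius
    P_all = curvatures.predictor_matrix()
    t_all = thickness.values
    areas = mesh.vertex_barycentric_area

    centers = np.flatnonzero(m)
    indptr, nbr_idx, nbr_dist = geodesic_neighborhoods(mesh, radius, centers=centers)

    tcorr = t_all.copy()
    betas = np.zeros((n, N_COEFFS))
    eff_n = np.zeros(n)
    flags = np.full(n, FLAG_IDENTITY, dtype=np.int8)
    flags[~m] = FLAG_OK  # only meaningful inside the mask

    for ci, c in enumerate(centers):
        J = nbr_idx[indptr[ci]:indptr[ci + 1]]
        D = nbr_dist[indptr[ci]:indptr[ci + 1]]
        keep = m[J]
        J, D = J[keep], D[keep]
        flag = FLAG_OK
        if len(J) < params.min_patch_vertices:
            nb = geodesic_neighborhood(mesh, int(c), 1.5 * radius)
            J, D = nb.vertices, nb.distances
            keep = m[J]
            J, D = J[keep], D[keep]
            flag = FLAG_EXPANDED
            if len(J) < params.min_patch_vertices:
                flags[c] = FLAG_IDENTITY
                betas[c, 0] = t_all[c]
                continue
        w = patch_weights(D, sigma, areas[J])
        center_pos = int(np.flatnonzero(J == c)[0])
        X, _ = _demeaned_design(P_all[J], w, center_pos)
        F = np.concatenate([P_all[c], P_all[c] ** 2])
        tJ = t_all[J]
        beta0, beta, ok = _wls_solve(X, w, tJ, params.ridge_eps)
        if not ok:
            Xl, Fl = X[:, :N_PREDICTORS], F[:N_PREDICTORS]
            beta0, bl, ok = _wls_solve(Xl, w, tJ, params.ridge_eps)
            if ok:
                beta = np.concatenate([bl, np.zeros(N_PREDICTORS)])
                flag = FLAG_LINEAR_ONLY
        if not ok:
            flags[c] = FLAG_IDENTITY
            betas[c, 0] = t_all[c]
            continue
        betas[c, 0] = beta0
        betas[c, 1:] = beta
        wn = w / w.sum()
        eff_n[c] = 1.0 / float((wn**2).sum())
        flags[c] = flag
        tcorr[c] = t_all[c] - float(F @ beta)

    fit = LocalFit(betas=betas, effective_n=eff_n, flags=flags)
    n_id = fit.n_fallback
    if n_id:
        logger.info("compensation: identity fallback at %d vertices", n_id)
    out = VertexMetric(tcorr, m.copy(), name="MRcorrThickness")
    return out, fit


# ------------------------------------------------------------- full pipeline

def compensate_pipeline(mesh: TriangleMesh, thickness: VertexMetric,
                        params: CompensationParams = CompensationParams(),
                        mask=None):
    """Regularization + curvature + local regression, in pipeline order.

    Stages: (1) geodesic-Gaussian smoothing of the surface coordinates,
    (2) curvature computation on the smoothed surface, (3) geodesic-Gaussian
    smoothing of the curvature maps, (4) local weighted regression of the
    (unsmoothed) thickness on the smoothed curvatures.  Resampling to a
    standard mesh, when needed, happens upstream via
    :func:`~intrinsic_thickness.regularize.resample_surface`.

    Returns ``(Tcorr, LocalFit, CurvatureSet)``.
    """
    smoothed = smooth_surface(mesh, params.surface_fwhm)
    curv = compute_all(smoothed, mask=mask)
    curv = curv.smoothed(smoothed, params.metric_fwhm)
    tcorr, fit = compensate_thickness(smoothed, thickness, curv, params, mask=mask)
    return tcorr, fit, curv
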