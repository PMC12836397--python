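"""Discrete curvature measures of cortical folding.

At every interior vertex p of a triangle mesh:

* mean curvature        H_p = (1/4) * sum_i ||l_i|| * beta_i / A_p
* Gaussian curvature    K_p = (2*pi - theta_p) / A_p

where the sum runs over the edges incident to p, ``l_i`` is the edge length,
``beta_i`` the signed dihedral angle at that edge, ``A_p`` the vertex area
(one third of the summed areas of the triangles meeting at p, so that vertex
areas partition the surface), and ``theta_p`` the sum of interior triangle
angles at p.  Principal curvatures follow from the quadratic relation

    k1 = H + sqrt(H^2 - K),   k2 = H - sqrt(H^2 - K)   (k1 >= k2),

and the Koenderink shape descriptors are

    SI = -(2/pi) * arctan((k1 + k2) / (k2 - k1))   in [-1, 1],
    C  = sqrt((k1^2 + k2^2) / 2)                   >= 0.

Sign convention: convex-with-respect-to-the-outward-normal (gyral) vertices
have H > 0 and SI > 0; concave (sulcal) vertices H < 0, SI < 0; saddles
SI ~ 0.  Because discrete H and K come from different operators, H^2 - K can
be slightly negative; the discriminant is clamped to 0 (umbilic) and the
fraction of clamped vertices is reported.

Boundary vertices are masked out: the angle-deficit formula is invalid there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import VertexMetric
from .mesh import TriangleMesh

logger = logging.getLogger(__name__)

__all__ = [
    "CurvatureSet",
    "mean_curvature",
    "gaussian_curvature",
    "principal_curvatures",
    "shape_index",
    "curvedness",
    "compute_all",
    "PREDICTOR_ORDER",
]

#: fixed regression-predictor order; H is excluded (collinear with k1, k2)
PREDICTOR_ORDER = ("k1", "k2", "K", "SI", "C")


@dataclass
class CurvatureSet:
    """The five folding predictors (k1, k2, K, SI, C) plus H, per vertex."""

    H: VertexMetric
    K: VertexMetric
    k1: VertexMetric
    k2: VertexMetric
    SI: VertexMetric
    C: VertexMetric
    clamped_fraction: float = 0.0
    planar_flags: np.ndarray | None = None

    @property
    def mask(self) -> np.ndarray:
        return self.H.mask

    def predictor_matrix(self) -> np.ndarray:
        """(n, 5) raw predictor values in the fixed order (k1, k2, K, SI, C)."""
        return np.column_stack(
            [getattr(self, name).values for name in PREDICTOR_ORDER]
        )

    def smoothed(self, mesh: TriangleMesh, fwhm: float) -> "CurvatureSet":
        """Geodesic-Gaussian smoothed copy of every curvature map."""
        from .regularize import metric_smoothing_matrix, smooth_metric

        if fwhm <= 0:
            return self
        W = metric_smoothing_matrix(mesh, fwhm, self.mask)
        kw = {
            f: smooth_metric(getattr(self, f), mesh, fwhm, _matrix=W)
            for f in ("H", "K", "k1", "k2", "SI", "C")
        }
        return CurvatureSet(
            clamped_fraction=self.clamped_fraction,
            planar_flags=self.planar_flags,
            **kw,
        )


def _interior_mask(mesh: TriangleMesh, mask=None) -> np.ndarray:
    m = ~mesh.is_boundary_vertex
    if mask is not None:
        m &= np.asarray(mask, dtype=bool)
    return m


def mean_curvature(mesh: TriangleMesh, mask=None) -> VertexMetric:
    """Vertex-wise discrete mean curvature H (mm^-1); boundary masked out.

    The denominator is the vertex area: one third of the summed adjacent
    triangle areas.  The thirds partition the surface (each triangle is
    shared by its three corners), which is what makes the estimator
    consistent — on a sphere of radius r it converges to 1/r.
    """
    A = mesh.vertex_barycentric_area
    if (A[_interior_mask(mesh)] <= 0).any():
        raise ValueError("degenerate one-ring: vertex with zero ring area")
    lengths = mesh.edge_lengths
    beta = mesh.edge_dihedral_angles
    contrib = np.where(np.isnan(beta), 0.0, lengths * beta)
    acc = np.zeros(mesh.n_vertices)
    np.add.at(acc, mesh.edges[:, 0], contrib)
    np.add.at(acc, mesh.edges[:, 1], contrib)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = 0.25 * acc / A
    H[~np.isfinite(H)] = 0.0
    return VertexMetric(H, _interior_mask(mesh, mask), name="H")


def gaussian_curvature(mesh: TriangleMesh, mask=None) -> VertexMetric:
    """Vertex-wise angle-deficit Gaussian curvature K (mm^-2); boundary masked out.

    Vertex-area (one-third ring) denominator, as for H: the angle deficits
    then integrate to 4*pi over a closed genus-0 surface with the vertex
    areas tiling the surface exactly once.
    """
    A = mesh.vertex_barycentric_area
    if (A[_interior_mask(mesh)] <= 0).any():
        raise ValueError("degenerate one-ring: vertex with zero ring area")
    with np.errstate(divide="ignore", invalid="ignore"):
        K = (2.0 * np.pi - mesh.interior_angle_sum) / A
    K[~np.isfinite(K)] = 0.0
    return VertexMetric(K, _interior_mask(mesh, mask), name="K")


def principal_curvatures(H: VertexMetric, K: VertexMetric,
                         tol_disc: float = 0.0):
    """(k1, k2) from H and K; negative discriminants clamped to umbilics.

    Returns ``(k1, k2, clamped_fraction)`` where the fraction counts in-mask
    vertices whose discriminant ``H^2 - K`` fell below ``-tol_disc``.
    """
    h, k = H.values, K.values
    disc = h * h - k
    mask = H.mask & K.mask
    clamped = mask & (disc < -tol_disc)
    frac = float(clamped.sum() / max(mask.sum(), 1))
    d = np.sqrt(np.maximum(disc, 0.0))
    k1 = VertexMetric(h + d, mask, name="k1")
    k2 = VertexMetric(h - d, mask, name="k2")
    return k1, k2, frac


def shape_index(k1: VertexMetric, k2: VertexMetric):
    """Koenderink shape index SI in [-1, 1]; planar points set to 0 and flagged."""
    a, b = k1.values, k2.values
    num = b + a
    den = b - a  # <= 0 since k1 >= k2
    planar = (a == 0) & (b == 0)
    umbilic = (den == 0) & ~planar
    si = np.zeros_like(a)
    ok = ~planar & ~umbilic
    si[ok] = -(2.0 / np.pi) * np.arctan(num[ok] / den[ok])
    si[umbilic] = np.sign(a[umbilic])  # dome +1, cup -1
    mask = k1.mask & k2.mask
    return VertexMetric(si, mask, name="SI"), planar


def curvedness(k1: VertexMetric, k2: VertexMetric) -> VertexMetric:
    """Curvedness C = sqrt((k1^2 + k2^2)/2) (mm^-1); zero only at planar points."""
    c = np.sqrt(0.5 * (k1.values ** 2 + k2.values ** 2))
    return VertexMetric(c, k1.mask & k2.mask, name="C")


def compute_all(mesh: TriangleMesh, mask=None) -> CurvatureSet:
    """Compute H, K, k1, k2, SI, C at every vertex of ``mesh``.

    Predictors export in the fixed order (k1, k2, K, SI, C); H is computed
    but excluded from the regression design because it is exactly collinear
    with (k1 + k2)/2.
    """
    H = mean_curvature(mesh, mask)
    K = gaussian_curvature(mesh, mask)
    k1, k2, frac = principal_curvatures(H, K)
    SI, planar = shape_index(k1, k2)
    C = curvedness(k1, k2)
    if frac > 0:
        logger.info("principal-curvature discriminant clamped at %.2f%% of vertices",
                    100 * frac)
    return CurvatureSet(H=H, K=K, k1=k1, k2=k2, SI=SI, C=C,
                        clamped_fraction=frac, planar_flags=planar)
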