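"""Synthetic surfaces and cohorts with analytically known geometry.

Real cortical-thickness cohorts are access-controlled, so every pipeline
stage is exercised on generated data whose ground truth is known exactly:

* ``make_icosphere`` — closed genus-0 meshes with constant analytic
  curvature (H = 1/r, K = 1/r^2, SI = +1, C = 1/r).
* ``make_folded_sheet`` — a triangulated sheet folded as
  ``z = A sin(2 pi x / lambda_x + phi_x) sin(2 pi y / lambda_y + phi_y)``,
  emulating gyri and sulci, with curvatures evaluated analytically from the
  Monge-patch fundamental forms at every vertex.
* ``make_cohort`` — a population of sheets sharing one intrinsic thickness
  map T0 but with per-subject random fold phases and amplitude jitter
  (inter-individual folding variability), thickness generated as

      T = T0 + g(x) * [sum_i a_i * curv_i + quadratic terms]
            + age_slope * (age - 60) + N(0, noise_sd)

  so the folding -> thickness effect, the aging effect, and the intrinsic
  map are all recoverable ground truth.  The smooth spatial gain g(x)
  makes the folding -> thickness coupling vary regionally, which is the
  regime that motivates a local (rather than one global) compensation
  model.

Sign conventions match the pipeline: sheet normals point +z, crests (gyri)
have H > 0 and SI > 0; ``sulc`` is the negated, demeaned fold height so
valleys are positive (FreeSurfer convention).

All randomness flows from one explicit integer seed; the same seed yields a
bit-identical cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .curvature import CurvatureSet, curvedness, principal_curvatures, shape_index
from .io_formats import ParcellationMap, VertexMetric
from .mesh import TriangleMesh, build_mesh

logger = logging.getLogger(__name__)

__all__ = [
    "SheetSpec",
    "ThicknessModel",
    "Subject",
    "SyntheticCohort",
    "make_icosphere",
    "make_folded_sheet",
    "make_cohort",
    "analytic_sheet_curvatures",
]


# ------------------------------------------------------------------ icosphere

def make_icosphere(radius: float = 1.0, subdivisions: int = 0) -> TriangleMesh:
    """Closed genus-0 icosphere: subdivided icosahedron projected to radius.

    The analytic curvature reference (H = 1/r, K = 1/r^2, k1 = k2 = 1/r,
    SI = +1, C = 1/r) is attached as ``mesh.analytic_reference``.
    """
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    tris = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    for _ in range(subdivisions):
        edge_mid: dict = {}
        new_verts = list(verts)

        def midpoint(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in edge_mid:
                m = new_verts[a] + new_verts[b]
                m = m / np.linalg.norm(m)
                edge_mid[key] = len(new_verts)
                new_verts.append(m)
            return edge_mid[key]

        new_tris = []
        for a, b, c in tris:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_tris += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(new_verts)
        tris = np.array(new_tris, dtype=np.int64)
    mesh = build_mesh(verts * radius, tris)
    mesh.analytic_reference = {
        "H": 1.0 / radius, "K": 1.0 / radius**2,
        "k1": 1.0 / radius, "k2": 1.0 / radius,
        "SI": 1.0, "C": 1.0 / radius,
    }
    return mesh


# --------------------------------------------------------------- folded sheet

@dataclass(frozen=True)
class SheetSpec:
    """Folded-sheet geometry: extent and fold amplitude/wavelength/phase.

    Defaults give a 60 x 60 mm sheet at 1 mm spacing with 20 mm folds of
    2.5 mm amplitude — three full gyrus/sulcus cycles per axis, so any 6 mm
    FWHM regression patch sees both inward and outward bending.
    """

    extent: tuple = (60.0, 60.0)
    spacing: float = 1.0
    amplitude: float = 2.5
    wavelength_x: float = 20.0
    wavelength_y: float = 20.0
    phase_x: float = 0.0
    phase_y: float = 0.0
    margin: int = 3

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.amplitude > 0:
            for lam in (self.wavelength_x, self.wavelength_y):
                if lam / self.spacing < 8:
                    raise ValueError(
                        f"undersampled fold: {lam / self.spacing:.1f} vertices per "
                        "wavelength (need >= 8)"
                    )
            if min(self.extent) < 2 * max(self.wavelength_x, self.wavelength_y):
                raise ValueError("extent must cover >= 2 full wavelengths")

    def grid(self):
        """(x, y) flat coordinate arrays of the vertex lattice."""
        nx = int(round(self.extent[0] / self.spacing)) + 1
        ny = int(round(self.extent[1] / self.spacing)) + 1
        xs = np.arange(nx) * self.spacing
        ys = np.arange(ny) * self.spacing
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        return X.ravel(), Y.ravel(), nx, ny


def _sheet_height_and_derivs(spec: SheetSpec, x, y):
    A = spec.amplitude
    wx = 2 * np.pi / spec.wavelength_x
    wy = 2 * np.pi / spec.wavelength_y
    ax = wx * x + spec.phase_x
    by = wy * y + spec.phase_y
    sx, cx = np.sin(ax), np.cos(ax)
    sy, cy = np.sin(by), np.cos(by)
    z = A * sx * sy
    return {
        "z": z,
        "zx": A * wx * cx * sy,
        "zy": A * wy * sx * cy,
        "zxx": -A * wx**2 * sx * sy,
        "zyy": -A * wy**2 * sx * sy,
        "zxy": A * wx * wy * cx * cy,
    }


def analytic_sheet_curvatures(spec: SheetSpec, mask: np.ndarray) -> CurvatureSet:
    """Exact Monge-patch curvatures of the sheet at every lattice vertex.

    Uses the first/second fundamental forms of the graph z(x, y), with the
    sign convention that upward crests (outward normal +z) have H > 0.
    """
    x, y, _, _ = spec.grid()
    d = _sheet_height_and_derivs(spec, x, y)
    zx, zy, zxx, zyy, zxy = d["zx"], d["zy"], d["zxx"], d["zyy"], d["zxy"]
    W2 = 1.0 + zx**2 + zy**2
    W = np.sqrt(W2)
    H = -((1 + zy**2) * zxx - 2 * zx * zy * zxy + (1 + zx**2) * zyy) / (2 * W2 * W)
    K = (zxx * zyy - zxy**2) / W2**2
    Hm = VertexMetric(H, mask, "H")
    Km = VertexMetric(K, mask, "K")
    k1, k2, frac = principal_curvatures(Hm, Km)
    SI, planar = shape_index(k1, k2)
    C = curvedness(k1, k2)
    return CurvatureSet(H=Hm, K=Km, k1=k1, k2=k2, SI=SI, C=C,
                        clamped_fraction=frac, planar_flags=planar)


def make_folded_sheet(spec: SheetSpec):
    """Build the folded sheet mesh plus its analytic curvatures and sulc map.

    Returns ``(mesh, analytic_curvatures, sulc)``.  The mask excludes
    ``spec.margin`` vertex rings at the sheet border (where one-rings are
    incomplete) in addition to the literal boundary ring.
    """
    x, y, nx, ny = spec.grid()
    d = _sheet_height_and_derivs(spec, x, y)
    verts = np.column_stack([x, y, d["z"]])

    ii, jj = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), indexing="ij")
    v00 = (ii * ny + jj).ravel()
    v10 = ((ii + 1) * ny + jj).ravel()
    v01 = (ii * ny + jj + 1).ravel()
    v11 = ((ii + 1) * ny + jj + 1).ravel()
    tris = np.concatenate(
        [np.column_stack([v00, v10, v11]), np.column_stack([v00, v11, v01])]
    )
    mesh = build_mesh(verts, tris)

    I, J = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ring = np.minimum(np.minimum(I, nx - 1 - I), np.minimum(J, ny - 1 - J)).ravel()
    mask = ring >= max(spec.margin, 1)

    curv = analytic_sheet_curvatures(spec, mask)
    sulc_vals = -(d["z"] - d["z"][mask].mean())
    sulc = VertexMetric(sulc_vals, mask, "sulc")
    return mesh, curv, sulc


# -------------------------------------------------------------------- cohorts

@dataclass(frozen=True)
class ThicknessModel:
    """Generative model for per-vertex thickness on a folded sheet.

    ``T = T0(x) + g(x) * f(folding) + age_slope * (age - age_ref) + noise``
    with ``f`` linear (plus optional quadratic) in the five curvature
    predictors (k1, k2, K, SI, C), or a tanh saturation of the linear term
    in model-mismatch mode.  T0 is ``base`` plus optional step edges along x
    (sharp areal borders).

    ``coeff_gain_range`` makes the folding -> thickness coupling vary
    smoothly across the sheet (a linear gain in x between the two bounds).
    This emulates the regional variation of the relationship that motivates
    a *local* compensation model: with a spatially uniform law, one global
    regression would already be the right model.  Set to ``None`` for a
    homogeneous law.
    """

    base: float = 2.5
    steps: tuple = ()  # ((x_mm, height_mm), ...)
    linear_coeffs: tuple = (1.5, 1.0, 0.0, 0.15, 0.0)
    quadratic_coeffs: tuple = (0.0,) * 5
    coeff_gain_range: tuple | None = (0.25, 1.75)
    age_slope: float = 0.0
    age_ref: float = 60.0
    noise_sd: float = 0.05
    mode: str = "linear"  # or "tanh"

    def t0(self, x: np.ndarray) -> np.ndarray:
        t = np.full_like(x, self.base, dtype=np.float64)
        for x0, h in self.steps:
            t = t + h * (x >= x0)
        if (t <= 0).any():
            raise ValueError("T0 must be positive everywhere")
        return t

    def coeff_gain(self, x: np.ndarray, extent_x: float) -> np.ndarray:
        if self.coeff_gain_range is None:
            return np.ones_like(x)
        lo, hi = self.coeff_gain_range
        return lo + (hi - lo) * x / extent_x

    def folding_term(self, curv: CurvatureSet, x: np.ndarray | None = None,
                     extent_x: float = 1.0) -> np.ndarray:
        P = curv.predictor_matrix()
        lin = P @ np.asarray(self.linear_coeffs, dtype=np.float64)
        quad = (P**2) @ np.asarray(self.quadratic_coeffs, dtype=np.float64)
        if self.mode == "tanh":
            scale = max(np.abs(lin).max(), 1e-12)
            f = scale * np.tanh((lin + quad) / scale)
        else:
            f = lin + quad
        if x is not None:
            f = self.coeff_gain(x, extent_x) * f
        return f


@dataclass
class Subject:
    """One synthetic participant: folded sheet plus thickness and sulc maps."""

    mesh: TriangleMesh
    thickness: VertexMetric
    sulc: VertexMetric
    curvatures: CurvatureSet  # analytic ground truth
    age: float
    spec: SheetSpec


@dataclass
class SyntheticCohort:
    """Subjects sharing intrinsic thickness T0, mask, grid, and parcellation."""

    subjects: list
    t0: VertexMetric
    mask: np.ndarray
    parcellation: ParcellationMap
    seed: int
    sheet_spec: SheetSpec
    model: ThicknessModel

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.subjects])

    def __len__(self) -> int:
        return len(self.subjects)


def _tile_parcellation(spec: SheetSpec, mask: np.ndarray, tiles: int = 4) -> ParcellationMap:
    x, y, _, _ = spec.grid()
    bx = np.clip((x / spec.extent[0] * tiles).astype(int), 0, tiles - 1)
    by = np.clip((y / spec.extent[1] * tiles).astype(int), 0, tiles - 1)
    labels = np.where(mask, bx * tiles + by + 1, 0)
    return ParcellationMap(labels)


def make_cohort(
    sheet_spec: SheetSpec = SheetSpec(),
    thickness_model: ThicknessModel = ThicknessModel(),
    n_subjects: int = 20,
    seed: int = 0,
    age_range: tuple = (36.0, 90.0),
    amplitude_jitter: float = 0.1,
    parcel_tiles: int = 4,
) -> SyntheticCohort:
    """Generate ``n_subjects`` folded sheets with subject-specific fold phases.

    Fold phases are uniform on [0, 2 pi); amplitudes are jittered by a
    uniform factor in [1 - amplitude_jitter, 1 + amplitude_jitter]; ages are
    uniform over ``age_range``.  Noise draws that would make thickness
    non-positive are redrawn (count logged).  Deterministic per seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    x, y, _, _ = sheet_spec.grid()
    subjects = []
    mask = None
    for _ in range(n_subjects):
        phases = rng.uniform(0.0, 2.0 * np.pi, size=2)
        amp = sheet_spec.amplitude * (1.0 + rng.uniform(-amplitude_jitter, amplitude_jitter))
        age = rng.uniform(*age_range)
        spec_i = SheetSpec(
            extent=sheet_spec.extent,
            spacing=sheet_spec.spacing,
            amplitude=amp,
            wavelength_x=sheet_spec.wavelength_x,
            wavelength_y=sheet_spec.wavelength_y,
            phase_x=phases[0],
            phase_y=phases[1],
            margin=sheet_spec.margin,
        )
        mesh, curv, sulc = make_folded_sheet(spec_i)
        if mask is None:
            mask = curv.mask.copy()
        t = (
            thickness_model.t0(x)
            + thickness_model.folding_term(curv, x, sheet_spec.extent[0])
            + thickness_model.age_slope * (age - thickness_model.age_ref)
        )
        if thickness_model.noise_sd > 0:
            noise = rng.normal(0.0, thickness_model.noise_sd, size=len(t))
            total = t + noise
            n_redrawn = 0
            for _ in range(100):
                bad = total <= 0
                if not bad.any():
                    break
                n_redrawn += int(bad.sum())
                noise[bad] = rng.normal(0.0, thickness_model.noise_sd, size=int(bad.sum()))
                total = t + noise
            if n_redrawn:
                logger.info("redrew %d noise values to keep thickness positive", n_redrawn)
            t = total
        subjects.append(
            Subject(
                mesh=mesh,
                thickness=VertexMetric(t, mask.copy(), "thickness"),
                sulc=sulc,
                curvatures=curv,
                age=float(age),
                spec=spec_i,
            )
        )
    t0 = VertexMetric(thickness_model.t0(x), mask.copy(), "T0")
    parc = _tile_parcellation(sheet_spec, mask, tiles=parcel_tiles)
    return SyntheticCohort(
        subjects=subjects,
        t0=t0,
        mask=mask,
        parcellation=parc,
        seed=seed,
        sheet_spec=sheet_spec,
        model=thickness_model,
    )
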