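"""Evaluation statistics for compensated and uncompensated thickness maps.

* ``spatial_gradient`` — vertex-wise gradient magnitude by local plane
  fitting in the tangent plane (sharp ridges mark candidate areal borders).
* ``cov_map`` — across-subject coefficient of variation per vertex
  (folding variability inflates it; compensation should reduce it).
* ``parcel_stats`` — group mean of per-subject parcel means and of
  per-subject within-parcel SDs (compensation homogenizes parcels that span
  gyri and sulci).
* ``age_effect`` — per-parcel OLS of thickness on age, with Cohen's
  f^2 = R^2 / (1 - R^2) and the area-weighted mean percent change in f^2
  between two metrics.
* ``shape_depth_table`` — mean thickness binned by shape index x sulcal
  depth, with per-subject empty-bin exclusion from the group average.

Sample SDs use the n-1 denominator throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ParcellationMap, VertexMetric
from .mesh import TriangleMesh

logger = logging.getLogger(__name__)

__all__ = [
    "ParcelStats",
    "AgeEffect",
    "ShapeDepthTable",
    "spatial_gradient",
    "cov_map",
    "parcel_stats",
    "age_effect",
    "compare_age_effects",
    "shape_depth_table",
]


# --------------------------------------------------------------- gradients

def spatial_gradient(mesh: TriangleMesh, metric: VertexMetric,
                     mask=None, two_ring: bool = False) -> VertexMetric:
    """Gradient magnitude of a surface map by local tangent-plane fitting.

    At each in-mask vertex, the one-ring (optionally two-ring) in-mask
    neighbors plus the vertex itself are projected into the tangent plane
    defined by the vertex normal; a least-squares plane
    ``value = c + g . (u, v)`` is fit and ``|g|`` returned (metric units per
    mm).  Vertices with fewer than 3 usable points are masked out.
    """
    m = metric.mask.copy()
    if mask is not None:
        m &= np.asarray(mask, bool)
    normals = mesh.vertex_normals
    verts = mesh.vertices
    vals = metric.values
    out = np.zeros(mesh.n_vertices)
    out_mask = np.zeros(mesh.n_vertices, dtype=bool)
    neighbors = mesh.vertex_neighbors
    for p in np.flatnonzero(m):
        ring = neighbors[p]
        if two_ring:
            ring = np.unique(np.concatenate([ring] + [neighbors[q] for q in ring]))
            ring = ring[ring != p]
        ring = ring[m[ring]]
        if len(ring) < 3:
            continue
        n = normals[p]
        # orthonormal tangent basis
        a = np.array([1.0, 0.0, 0.0])
        if abs(n[0]) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        u = np.cross(n, a)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        rel = verts[ring] - verts[p]
        U = rel @ u
        V = rel @ v
        A = np.column_stack([np.ones(len(ring) + 1),
                             np.concatenate([[0.0], U]),
                             np.concatenate([[0.0], V])])
        y = np.concatenate([[vals[p]], vals[ring]])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        out[p] = float(np.hypot(coef[1], coef[2]))
        out_mask[p] = True
    dropped = int(m.sum() - out_mask.sum())
    if dropped:
        logger.info("gradient: %d vertices under-determined and masked", dropped)
    return VertexMetric(out, out_mask, name=f"grad({metric.name})")


# --------------------------------------------------------- cross-subject CoV

def cov_map(subject_metrics, mask=None) -> VertexMetric:
    """Across-subject coefficient of variation (SD / mean) per vertex.

    Vertices where the across-subject mean is <= 0 are masked out (counted);
    the common mask is the intersection of all subject masks.
    """
    if len(subject_metrics) < 2:
        raise ValueError("need at least 2 subjects")
    vals = np.stack([s.values for s in subject_metrics])
    m = np.logical_and.reduce([s.mask for s in subject_metrics])
    if mask is not None:
        m &= np.asarray(mask, bool)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    bad = m & (mean <= 0)
    if bad.any():
        logger.info("cov_map: %d vertices with nonpositive mean masked", int(bad.sum()))
    m = m & (mean > 0)
    cov = np.zeros(vals.shape[1])
    cov[m] = sd[m] / mean[m]
    return VertexMetric(cov, m, name="CoV")


# ------------------------------------------------------------ parcel stats

@dataclass
class ParcelStats:
    """Across-subject parcel summary: group means of per-subject mean and SD."""

    table: pd.DataFrame  # index: parcel id; columns: mean, within_sd, area_mm2, n_subjects
    excluded_parcels: list = field(default_factory=list)


def parcel_stats(subject_metrics, parcellation: ParcellationMap,
                 mesh: TriangleMesh, mask=None) -> ParcelStats:
    """Per parcel: mean over subjects of (per-subject mean, per-subject SD).

    Per-subject statistics use only that subject's in-mask member vertices;
    parcels with no in-mask vertices are excluded and reported.
    """
    areas = parcellation.parcel_areas(mesh)
    rows = {}
    excluded = []
    for pid in parcellation.parcel_ids:
        sel = parcellation.labels == pid
        means, sds = [], []
        for s in subject_metrics:
            mm = sel & s.mask
            if mask is not None:
                mm &= np.asarray(mask, bool)
            v = s.values[mm]
            if len(v) == 0:
                continue
            means.append(v.mean())
            sds.append(v.std(ddof=1) if len(v) > 1 else 0.0)
        if not means:
            excluded.append(int(pid))
            continue
        rows[int(pid)] = {
            "mean": float(np.mean(means)),
            "within_sd": float(np.mean(sds)),
            "area_mm2": areas[int(pid)],
            "n_subjects": len(means),
        }
    if excluded:
        logger.info("parcel_stats: %d parcels had no in-mask vertices", len(excluded))
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "parcel"
    return ParcelStats(table=table, excluded_parcels=excluded)


# -------------------------------------------------------------- age effects

@dataclass
class AgeEffect:
    """Per-parcel age regression: slope (mm/yr), R^2, and Cohen's f^2."""

    table: pd.DataFrame  # index: parcel id; columns: slope, r2, f2, area_mm2


def _f2(r2: np.ndarray) -> np.ndarray:
    if np.any(r2 >= 1.0):
        raise ValueError("f^2 undefined at R^2 = 1")
    return r2 / (1.0 - r2)


def age_effect(parcel_values: pd.DataFrame, ages: np.ndarray,
               parcel_areas: dict) -> AgeEffect:
    """OLS of per-subject parcel means on age, per parcel.

    ``parcel_values`` has one row per subject and one column per parcel id.
    Cohen's f^2 = R^2 / (1 - R^2): explained over unexplained variance.
    """
    ages = np.asarray(ages, dtype=np.float64)
    if len(ages) < 3:
        raise ValueError("need at least 3 subjects")
    if ages.std() == 0:
        raise ValueError("zero age variance")
    a = ages - ages.mean()
    rows = {}
    for pid in parcel_values.columns:
        y = parcel_values[pid].to_numpy(dtype=np.float64)
        yc = y - y.mean()
        denom = (a**2).sum()
        slope = (a @ yc) / denom
        ss_tot = (yc**2).sum()
        if ss_tot == 0:
            r2 = 0.0
        else:
            resid = yc - slope * a
            r2 = 1.0 - (resid**2).sum() / ss_tot
        rows[int(pid)] = {
            "slope": float(slope),
            "r2": float(r2),
            "f2": float(_f2(np.array(r2))),
            "area_mm2": float(parcel_areas.get(int(pid), np.nan)),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "parcel"
    return AgeEffect(table=table)


def compare_age_effects(effect_a: AgeEffect, effect_b: AgeEffect) -> dict:
    """Effect-size change of metric A relative to metric B, per parcel and pooled.

    Returns the per-parcel percent change of f^2 and the area-weighted mean
    percent change (positive where A shows the stronger aging effect).
    """
    ta, tb = effect_a.table, effect_b.table
    common = ta.index.intersection(tb.index)
    fa = ta.loc[common, "f2"].to_numpy()
    fb = tb.loc[common, "f2"].to_numpy()
    areas = ta.loc[common, "area_mm2"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (fa - fb) / fb
    ok = np.isfinite(pct)
    weighted = float((pct[ok] * areas[ok]).sum() / areas[ok].sum())
    return {
        "per_parcel_pct_change": pd.Series(pct, index=common),
        "area_weighted_pct_change": weighted,
        "fraction_parcels_increased": float((fa > fb).mean()),
    }


# -------------------------------------------------------- shape/depth table

@dataclass
class ShapeDepthTable:
    """Group-mean thickness over shape-index x sulcal-depth bins."""

    values: np.ndarray  # (n_si_bins, n_sulc_bins), NaN where empty for all subjects
    counts: np.ndarray  # subjects contributing per cell
    si_edges: np.ndarray
    sulc_edges: np.ndarray

    @property
    def value_range(self) -> float:
        v = self.values[np.isfinite(self.values)]
        return float(v.max() - v.min()) if v.size else float("nan")


def _bin_index(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open bins [lo, hi), final bin closed; -1 outside the range."""
    idx = np.searchsorted(edges, x, side="right") - 1
    idx[x == edges[-1]] = len(edges) - 2
    idx[(x < edges[0]) | (x > edges[-1])] = -1
    return idx


def shape_depth_table(subject_data, si_edges=None, sulc_edges=None,
                      mask=None) -> ShapeDepthTable:
    """Mean thickness per (shape index, sulc) bin, averaged across subjects.

    ``subject_data`` is a sequence of ``(thickness, si, sulc)`` metric
    triples.  Per subject, each cell's mean uses that subject's in-mask
    vertices falling in the cell; subjects with an empty cell are excluded
    from that cell's group mean (its count drops accordingly).

    Default bins: shape index in 10 equal bins over [-1, 1]; sulc in 10
    equal-count bins pooled over subjects.
    """
    if si_edges is None:
        si_edges = np.linspace(-1.0, 1.0, 11)
    si_edges = np.asarray(si_edges, dtype=np.float64)
    if sulc_edges is None:
        pooled = np.concatenate([
            s.values[s.mask if mask is None else (s.mask & mask)]
            for _, _, s in subject_data
        ])
        sulc_edges = np.quantile(pooled, np.linspace(0, 1, 11))
    sulc_edges = np.asarray(sulc_edges, dtype=np.float64)
    nsi, nsu = len(si_edges) - 1, len(sulc_edges) - 1
    acc = np.zeros((nsi, nsu))
    counts = np.zeros((nsi, nsu), dtype=np.int64)
    for thickness, si, sulc in subject_data:
        m = thickness.mask & si.mask & sulc.mask
        if mask is not None:
            m &= np.asarray(mask, bool)
        bi = _bin_index(si.values, si_edges)
        bj = _bin_index(sulc.values, sulc_edges)
        ok = m & (bi >= 0) & (bj >= 0)
        flat = bi[ok] * nsu + bj[ok]
        sums = np.bincount(flat, weights=thickness.values[ok], minlength=nsi * nsu)
        ns = np.bincount(flat, minlength=nsi * nsu)
        has = ns > 0
        cell_mean = np.zeros(nsi * nsu)
        cell_mean[has] = sums[has] / ns[has]
        acc += np.where(has, cell_mean, 0.0).reshape(nsi, nsu)
        counts += has.reshape(nsi, nsu)
    values = np.full((nsi, nsu), np.nan)
    nz = counts > 0
    values[nz] = acc[nz] / counts[nz]
    return ShapeDepthTable(values=values, counts=counts,
                           si_edges=si_edges, sulc_edges=sulc_edges)
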