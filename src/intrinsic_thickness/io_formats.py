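"""Surface and metric I/O: GIFTI and FreeSurfer binary dialects.

Maps on-disk formats to the in-memory types used throughout the pipeline:

* surfaces (GIFTI ``.surf.gii`` with POINTSET+TRIANGLE intents, or FreeSurfer
  binary surfaces) -> :class:`~intrinsic_thickness.mesh.TriangleMesh`
* per-vertex scalars (GIFTI ``.func.gii`` / ``.shape.gii``, or FreeSurfer
  curv/sulc files) -> :class:`VertexMetric`
* integer label maps (GIFTI ``.label.gii`` or plain shape files)
  -> :class:`ParcellationMap`

Vertex indexing is 0-based everywhere, matching both on-disk conventions.
Non-finite metric values on read become masked-out vertices (count logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import nibabel as nib
from nibabel import gifti
from nibabel.freesurfer import io as fsio

from .mesh import TriangleMesh, build_mesh

logger = logging.getLogger(__name__)

__all__ = [
    "VertexMetric",
    "ParcellationMap",
    "read_surface",
    "write_surface",
    "read_metric",
    "write_metric",
    "read_parcellation",
]


@dataclass
class VertexMetric:
    """Per-vertex scalar field tied to a mesh.

    ``mask`` is True where the vertex is inside the analysis region (not
    medial wall / boundary); masked-out vertices may hold any placeholder and
    are excluded from every statistic.  An absent mask means all-true.
    """

    values: np.ndarray
    mask: np.ndarray | None = None
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.mask is None:
            self.mask = np.ones(len(self.values), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if len(self.mask) != len(self.values):
                raise ValueError("mask length does not match values length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def masked_values(self) -> np.ndarray:
        """Values at in-mask vertices only."""
        return self.values[self.mask]

    def with_values(self, values, name: str | None = None) -> "VertexMetric":
        return VertexMetric(values, self.mask.copy(), name if name is not None else self.name)

    def intersect_mask(self, other_mask: np.ndarray) -> "VertexMetric":
        return VertexMetric(self.values, self.mask & other_mask, self.name)


@dataclass
class ParcellationMap:
    """Integer label per vertex; 0 means unassigned / medial wall."""

    labels: np.ndarray
    names: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if (self.labels < 0).any():
            raise ValueError("parcel labels must be nonnegative")
        for lab in self.parcel_ids:
            self.names.setdefault(int(lab), f"parcel_{int(lab)}")

    @property
    def parcel_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def parcel_areas(self, mesh: TriangleMesh) -> dict:
        """Surface area per parcel: one-third of incident triangle areas per member vertex."""
        a = mesh.vertex_barycentric_area
        return {
            int(lab): float(a[self.labels == lab].sum()) for lab in self.parcel_ids
        }


# --------------------------------------------------------------------- GIFTI

_INTENT_POINTSET = "NIFTI_INTENT_POINTSET"
_INTENT_TRIANGLE = "NIFTI_INTENT_TRIANGLE"


def _detect_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    p = str(path)
    return "gifti" if p.endswith(".gii") else "freesurfer"


def read_surface(path, fmt: str | None = None, validate: bool = True) -> TriangleMesh:
    """Read a surface mesh from GIFTI (.surf.gii) or FreeSurfer binary format.

    Coordinates are taken as mm; triangle winding is preserved as stored.
    """
    fmt = _detect_format(path, fmt)
    if fmt == "gifti":
        img = nib.load(str(path))
        if not isinstance(img, gifti.GiftiImage):
            raise ValueError(f"{path}: not a GIFTI file")
        pts = img.get_arrays_from_intent(_INTENT_POINTSET)
        tris = img.get_arrays_from_intent(_INTENT_TRIANGLE)
        if not pts or not tris:
            raise ValueError(
                f"{path}: GIFTI file lacks POINTSET/TRIANGLE arrays (not a surface)"
            )
        vertices = pts[0].data.astype(np.float64)
        triangles = tris[0].data.astype(np.int64)
    elif fmt == "freesurfer":
        vertices, triangles = fsio.read_geometry(str(path))
    else:
        raise ValueError(f"unknown surface format {fmt!r}")
    return build_mesh(vertices, triangles, validate=validate)


def write_surface(mesh: TriangleMesh, path, fmt: str | None = None) -> None:
    """Write a surface mesh as GIFTI (.surf.gii) or FreeSurfer binary."""
    fmt = _detect_format(path, fmt)
    if fmt == "gifti":
        img = gifti.GiftiImage(
            darrays=[
                gifti.GiftiDataArray(
                    mesh.vertices.astype(np.float32), intent=_INTENT_POINTSET
                ),
                gifti.GiftiDataArray(
                    mesh.triangles.astype(np.int32), intent=_INTENT_TRIANGLE
                ),
            ]
        )
        nib.save(img, str(path))
    elif fmt == "freesurfer":
        fsio.write_geometry(str(path), mesh.vertices, mesh.triangles)
    else:
        raise ValueError(f"unknown surface format {fmt!r}")


def read_metric(path, fmt: str | None = None, n_vertices: int | None = None,
                name: str = "") -> VertexMetric:
    """Read a per-vertex scalar map (GIFTI func/shape or FreeSurfer curv).

    Non-finite values are converted to masked-out vertices with a logged
    count.  If ``n_vertices`` is given, a length mismatch is an error.
    """
    fmt = _detect_format(path, fmt)
    if fmt == "gifti":
        img = nib.load(str(path))
        if not isinstance(img, gifti.GiftiImage):
            raise ValueError(f"{path}: not a GIFTI file")
        if not img.darrays:
            raise ValueError(f"{path}: GIFTI file has no data arrays")
        values = img.darrays[0].data.astype(np.float64)
    elif fmt == "freesurfer":
        values = fsio.read_morph_data(str(path)).astype(np.float64)
    else:
        raise ValueError(f"unknown metric format {fmt!r}")
    if values.ndim != 1:
        values = values.ravel()
    if n_vertices is not None and len(values) != n_vertices:
        raise ValueError(
            f"{path}: metric has {len(values)} values but mesh has {n_vertices} vertices"
        )
    mask = np.isfinite(values)
    n_bad = int((~mask).sum())
    if n_bad:
        logger.warning("%s: %d non-finite values masked out", path, n_bad)
        values = np.where(mask, values, 0.0)
    return VertexMetric(values, mask, name=name or str(path))


def write_metric(metric: VertexMetric, path, fmt: str | None = None) -> None:
    """Write a per-vertex scalar map; masked-out vertices are stored as NaN."""
    fmt = _detect_format(path, fmt)
    values = np.where(metric.mask, metric.values, np.nan)
    if fmt == "gifti":
        da = gifti.GiftiDataArray(values.astype(np.float32), intent="NIFTI_INTENT_NONE")
        nib.save(gifti.GiftiImage(darrays=[da]), str(path))
    elif fmt == "freesurfer":
        fsio.write_morph_data(str(path), values)
    else:
        raise ValueError(f"unknown metric format {fmt!r}")


def read_parcellation(path, fmt: str | None = None,
                      n_vertices: int | None = None) -> ParcellationMap:
    """Read an integer label map (GIFTI label/shape file or FreeSurfer curv)."""
    fmt = _detect_format(path, fmt)
    names = {}
    if fmt == "gifti":
        img = nib.load(str(path))
        labels = np.rint(img.darrays[0].data).astype(np.int64)
        if img.labeltable is not None:
            for lab in img.labeltable.labels:
                if lab.key and lab.label:
                    names[int(lab.key)] = lab.label
    else:
        labels = np.rint(fsio.read_morph_data(str(path))).astype(np.int64)
    if n_vertices is not None and len(labels) != n_vertices:
        raise ValueError(
            f"{path}: label map has {len(labels)} values but mesh has {n_vertices} vertices"
        )
    return ParcellationMap(labels, names)
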