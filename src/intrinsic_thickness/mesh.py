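"""Triangle-mesh substrate: combinatorics, differential-geometry primitives, geodesics.

Every downstream quantity (curvature, smoothing kernels, regression patches)
is built from the per-vertex and per-edge quantities cached on
:class:`TriangleMesh`:

* one-ring neighbor lists and one-ring total triangle area ``A`` (mm^2),
* per-triangle areas and unit normals, area-weighted vertex normals,
* per-edge lengths ``|l|`` (mm) and signed dihedral angles ``beta`` (radians),
* per-vertex interior-angle sums ``theta_p`` (radians).

Sign convention: the dihedral angle at an edge is POSITIVE where the surface
is locally convex with respect to the outward normal (gyral ridge) and
NEGATIVE where concave (sulcal valley).  A closed sphere with outward-wound
triangles therefore has all-positive dihedrals.

Geodesic distances are single-source shortest paths on the edge graph with
Euclidean edge lengths (an upper bound on the true polyhedral geodesic
distance), truncated at the query radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

logger = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "GeodesicNeighborhood",
    "MeshError",
    "build_mesh",
    "geodesic_neighborhood",
    "geodesic_neighborhoods",
]


class MeshError(ValueError):
    """Raised for non-manifold, degenerate, or inconsistently wound meshes."""


@dataclass(frozen=True)
class GeodesicNeighborhood:
    """Vertices within a geodesic radius of a center vertex.

    ``distances`` are edge-graph shortest-path distances in mm; the center is
    always included with distance 0.
    """

    center: int
    vertices: np.ndarray
    distances: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be nonnegative")


class TriangleMesh:
    """Immutable triangle mesh with lazily computed, cached derived quantities.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    triangles : (m, 3) int array
        Vertex-index triples; consistent counter-clockwise winding seen from
        the outward normal side.
    validate : bool
        Run manifold / degeneracy / winding checks (on by default).
    """

    def __init__(self, vertices, triangles, validate: bool = True):
        self.vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshError("triangles must be an (m, 3) array")
        if validate:
            self._validate()

    # ------------------------------------------------------------------ basic
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def _validate(self) -> None:
        t = self.triangles
        if t.size and (t.min() < 0 or t.max() >= self.n_vertices):
            raise MeshError("triangle index out of range")
        if ((t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])).any():
            raise MeshError("triangle with repeated vertex index")
        if (self.triangle_areas <= 0).any() or not np.isfinite(self.triangle_areas).all():
            bad = int(np.argmin(self.triangle_areas))
            raise MeshError(f"zero-area (degenerate) triangle at index {bad}")
        # manifold: every undirected edge in <= 2 triangles
        counts = self._edge_counts
        if (counts > 2).any():
            e = self.edges[np.argmax(counts)]
            raise MeshError(f"non-manifold edge {tuple(e)}: more than 2 incident triangles")
        # winding: each interior undirected edge must appear once per direction
        if self._winding_conflicts:
            raise MeshError(
                f"inconsistent winding at edges {self._winding_conflicts[:5]}"
            )

    # ----------------------------------------------------------------- edges
    @cached_property
    def _directed_edges(self) -> np.ndarray:
        """(3m, 2) directed edges; row 3*f+j is edge j of triangle f."""
        t = self.triangles
        return np.concatenate(
            [t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]], axis=0
        ).reshape(3, -1, 2).transpose(1, 0, 2).reshape(-1, 2)

    @cached_property
    def _edge_topology(self):
        de = self._directed_edges
        und = np.sort(de, axis=1)
        edges, inverse, counts = np.unique(
            und, axis=0, return_inverse=True, return_counts=True
        )
        return edges, inverse, counts

    @property
    def edges(self) -> np.ndarray:
        """(E, 2) undirected edges, each row sorted ascending."""
        return self._edge_topology[0]

    @property
    def _edge_counts(self) -> np.ndarray:
        return self._edge_topology[2]

    @cached_property
    def _edge_triangles(self) -> np.ndarray:
        """(E, 2) incident triangle indices per undirected edge, -1 if absent.

        Column 0 holds the triangle traversing the edge in sorted (lo->hi)
        direction, column 1 the one traversing hi->lo.
        """
        de = self._directed_edges
        _, inverse, _ = self._edge_topology
        tri_of_row = np.repeat(np.arange(self.n_triangles), 3)
        forward = de[:, 0] < de[:, 1]
        out = np.full((len(self.edges), 2), -1, dtype=np.int64)
        out[inverse[forward], 0] = tri_of_row[forward]
        out[inverse[~forward], 1] = tri_of_row[~forward]
        return out

    @cached_property
    def _winding_conflicts(self) -> list:
        """Interior edges traversed twice in the same direction."""
        de = self._directed_edges
        _, inverse, counts = self._edge_topology
        forward = de[:, 0] < de[:, 1]
        nf = np.zeros(len(counts), dtype=np.int64)
        np.add.at(nf, inverse[forward], 1)
        bad = np.flatnonzero((counts == 2) & (nf != 1))
        return [tuple(self.edges[b]) for b in bad]

    @cached_property
    def boundary_edges(self) -> np.ndarray:
        """Indices (into ``edges``) of edges with exactly one incident triangle."""
        return np.flatnonzero(self._edge_counts == 1)

    @cached_property
    def boundary_vertices(self) -> np.ndarray:
        """Sorted array of vertex indices lying on a boundary edge."""
        return np.unique(self.edges[self.boundary_edges])

    @cached_property
    def is_boundary_vertex(self) -> np.ndarray:
        m = np.zeros(self.n_vertices, dtype=bool)
        m[self.boundary_vertices] = True
        return m

    @cached_property
    def edge_lengths(self) -> np.ndarray:
        """Euclidean length (mm) per undirected edge."""
        e = self.edges
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    # ------------------------------------------------------------- triangles
    @cached_property
    def _triangle_cross(self) -> np.ndarray:
        t = self.triangles
        v = self.vertices
        return np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])

    @cached_property
    def triangle_areas(self) -> np.ndarray:
        """Area (mm^2) per triangle."""
        return 0.5 * np.linalg.norm(self._triangle_cross, axis=1)

    @cached_property
    def triangle_normals(self) -> np.ndarray:
        """Unit normal per triangle (right-hand rule on the winding)."""
        c = self._triangle_cross
        return c / np.linalg.norm(c, axis=1, keepdims=True)

    @cached_property
    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident triangle normals, normalized."""
        n = np.zeros_like(self.vertices)
        w = self.triangle_normals * self.triangle_areas[:, None]
        for j in range(3):
            np.add.at(n, self.triangles[:, j], w)
        norms = np.linalg.norm(n, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return n / norms

    @cached_property
    def vertex_ring_area(self) -> np.ndarray:
        """One-ring total area A per vertex: sum of incident triangle areas (mm^2)."""
        a = np.zeros(self.n_vertices)
        for j in range(3):
            np.add.at(a, self.triangles[:, j], self.triangle_areas)
        return a

    @cached_property
    def vertex_barycentric_area(self) -> np.ndarray:
        """One-third of the one-ring area (mm^2): a partition of total area."""
        return self.vertex_ring_area / 3.0

    # ---------------------------------------------------------------- angles
    @cached_property
    def interior_angle_sum(self) -> np.ndarray:
        """theta_p: sum of triangle corner angles meeting at each vertex (radians)."""
        v = self.vertices
        t = self.triangles
        theta = np.zeros(self.n_vertices)
        for j in range(3):
            p = v[t[:, j]]
            a = v[t[:, (j + 1) % 3]] - p
            b = v[t[:, (j + 2) % 3]] - p
            cosang = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            np.add.at(theta, t[:, j], np.arccos(np.clip(cosang, -1.0, 1.0)))
        return theta

    @cached_property
    def edge_dihedral_angles(self) -> np.ndarray:
        """Signed dihedral angle (radians) per undirected edge; NaN on boundary.

        Positive where the fold is convex with respect to the outward normals
        (sign of ``dot(n1 x n2, edge vector as traversed by triangle 1)``).
        """
        et = self._edge_triangles
        beta = np.full(len(self.edges), np.nan)
        interior = (et[:, 0] >= 0) & (et[:, 1] >= 0)
        n1 = self.triangle_normals[et[interior, 0]]
        n2 = self.triangle_normals[et[interior, 1]]
        e = self.edges[interior]
        # triangle in column 0 traverses lo->hi
        evec = self.vertices[e[:, 1]] - self.vertices[e[:, 0]]
        cosb = np.clip(np.einsum("ij,ij->i", n1, n2), -1.0, 1.0)
        sign = np.sign(np.einsum("ij,ij->i", np.cross(n1, n2), evec))
        sign[sign == 0] = 1.0
        beta[interior] = sign * np.arccos(cosb)
        return beta

    # ------------------------------------------------------------- adjacency
    @cached_property
    def vertex_neighbors(self) -> list:
        """One-ring neighbor index array per vertex."""
        e = self.edges
        nbr = [[] for _ in range(self.n_vertices)]
        for a, b in e:
            nbr[a].append(b)
            nbr[b].append(a)
        return [np.array(sorted(x), dtype=np.int64) for x in nbr]

    @cached_property
    def vertex_edges(self) -> list:
        """Indices (into ``edges``) of edges incident to each vertex."""
        e = self.edges
        inc = [[] for _ in range(self.n_vertices)]
        for i, (a, b) in enumerate(e):
            inc[a].append(i)
            inc[b].append(i)
        return [np.array(x, dtype=np.int64) for x in inc]

    @cached_property
    def edge_graph(self) -> csr_matrix:
        """Symmetric sparse adjacency weighted by Euclidean edge length."""
        e = self.edges
        L = self.edge_lengths
        n = self.n_vertices
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        data = np.concatenate([L, L])
        return csr_matrix((data, (rows, cols)), shape=(n, n))

    @cached_property
    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges) + self.n_triangles


def build_mesh(vertices, triangles, validate: bool = True) -> TriangleMesh:
    """Construct and validate a :class:`TriangleMesh`.

    Raises :class:`MeshError` on non-manifold edges, degenerate triangles or
    inconsistent winding; meshes are rejected, never silently repaired.
    """
    return TriangleMesh(vertices, triangles, validate=validate)


def geodesic_neighborhood(mesh: TriangleMesh, center: int, radius: float) -> GeodesicNeighborhood:
    """All vertices within geodesic (edge-graph) ``radius`` mm of ``center``."""
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    if not 0 <= center < mesh.n_vertices:
        raise IndexError(f"center {center} out of range")
    dist = dijkstra(mesh.edge_graph, indices=center, limit=radius)
    inside = np.flatnonzero(dist <= radius)
    order = np.argsort(dist[inside], kind="stable")
    inside = inside[order]
    return GeodesicNeighborhood(
        center=center,
        vertices=inside,
        distances=dist[inside],
        radius=float(radius),
    )


def geodesic_neighborhoods(
    mesh: TriangleMesh,
    radius: float,
    centers: np.ndarray | None = None,
    chunk: int = 512,
):
    """Truncated geodesic distances from many centers at once.

    Returns ``(indptr, indices, dists)`` in CSR layout: the neighborhood of
    ``centers[i]`` is ``indices[indptr[i]:indptr[i+1]]`` with matching
    distances.  Each neighborhood includes its center at distance 0.
    Chunked so peak memory stays at ``chunk * n_vertices`` doubles.
    """
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    if centers is None:
        centers = np.arange(mesh.n_vertices)
    centers = np.asarray(centers, dtype=np.int64)
    g = mesh.edge_graph
    indptr = [0]
    idx_parts = []
    dist_parts = []
    for start in range(0, len(centers), chunk):
        sub = centers[start : start + chunk]
        d = dijkstra(g, indices=sub, limit=radius)
        d = np.atleast_2d(d)
        for row in d:
            inside = np.flatnonzero(row <= radius)
            idx_parts.append(inside)
            dist_parts.append(row[inside])
            indptr.append(indptr[-1] + len(inside))
    return (
        np.array(indptr, dtype=np.int64),
        np.concatenate(idx_parts) if idx_parts else np.array([], dtype=np.int64),
        np.concatenate(dist_parts) if dist_parts else np.array([], dtype=np.float64),
    )
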