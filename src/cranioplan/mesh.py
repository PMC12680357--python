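"""Triangle-mesh container, STL I/O and the geometric measurements used pipeline-wide.

All coordinates are millimetres.  Meshes are carried as explicit
vertex/face arrays (shared-topology correspondence is the backbone of the
shape-modelling stage, so vertex ordering is significant and is never
silently reindexed); :mod:`trimesh` does the heavy lifting for STL parsing,
normals, closest-point queries and volume integrals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "TriangleMesh",
    "SurfaceDistanceMap",
    "load_stl",
    "save_stl",
    "flatten_shape",
    "unflatten_shape",
    "surface_distance",
    "export_heatmap_ply",
    "cranial_index",
    "mesh_volume",
    "offset_mesh",
    "volume_match_scale",
]

# STL stores a triangle soup; shared vertices are recovered on read by
# merging vertices closer than this tolerance (mm).
STL_MERGE_TOL = 1e-6


@dataclass
class TriangleMesh:
    """A triangulated surface: ``vertices`` (n, 3) float64 mm, ``faces`` (m, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if len(self.vertices) == 0 or len(self.faces) == 0:
            raise ValueError("mesh is empty")
        if not np.isfinite(self.vertices).all():
            raise ValueError("vertex coordinates must be finite")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        """View as a :class:`trimesh.Trimesh` without reindexing vertices."""
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same topology, new geometry."""
        return TriangleMesh(np.asarray(vertices, dtype=np.float64), self.faces.copy())


@dataclass
class SurfaceDistanceMap:
    """Per-vertex unsigned distance (mm) from a query mesh to a reference surface."""

    distances: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if (self.distances < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.distances.mean())

    @property
    def max(self) -> float:
        return float(self.distances.max())

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.distances, q))

    def to_csv(self, path: str | Path) -> None:
        """Export as ``vertex_index,distance_mm`` rows for heatmap rendering."""
        idx = np.arange(len(self.distances))
        arr = np.column_stack([idx, self.distances])
        np.savetxt(path, arr, fmt=["%d", "%.6f"], delimiter=",",
                   header="vertex_index,distance_mm", comments="")


def export_heatmap_ply(mesh: TriangleMesh, scalars: np.ndarray, path: str | Path) -> None:
    """Write an ASCII PLY with one scalar per vertex (a ``quality`` property).

    Viewers render the scalar as a heatmap; used for surface-error maps.
    """
    scalars = np.asarray(scalars, dtype=float)
    if len(scalars) != mesh.n_vertices:
        raise ValueError("need one scalar per vertex")
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float quality\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v, q in zip(mesh.vertices, scalars):
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} {q:.6f}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def load_stl(path: str | Path) -> TriangleMesh:
    """Read a binary or ASCII STL and merge coincident vertices.

    STL files carry disconnected triangles; vertices within
    ``STL_MERGE_TOL`` mm are merged so downstream stages see shared
    topology.
    """
    try:
        tm = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except Exception as exc:  # malformed file
        raise ValueError(f"cannot parse STL file {path!s}: {exc}") from exc
    if tm.vertices.shape[0] == 0 or tm.faces.shape[0] == 0:
        raise ValueError(f"STL file {path!s} contains no triangles")
    tm.merge_vertices(digits_vertex=int(-np.log10(STL_MERGE_TOL)))
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def save_stl(mesh: TriangleMesh, path: str | Path, ascii: bool = False) -> None:
    """Write a mesh to binary (default) or ASCII STL."""
    tm = mesh.to_trimesh()
    data = trimesh.exchange.stl.export_stl_ascii(tm) if ascii else trimesh.exchange.stl.export_stl(tm)
    mode = "w" if ascii else "wb"
    with open(path, mode) as fh:
        fh.write(data)


def flatten_shape(mesh: TriangleMesh) -> np.ndarray:
    """Vectorise a mesh as ``[x1, y1, z1, ..., xN, yN, zN]`` (length 3N)."""
    return mesh.vertices.reshape(-1).copy()


def unflatten_shape(vector: np.ndarray, faces: np.ndarray) -> TriangleMesh:
    """Inverse of :func:`flatten_shape` given the face topology."""
    vector = np.asarray(vector, dtype=np.float64)
    if vector.ndim != 1 or vector.size % 3 != 0:
        raise ValueError("shape vector length must be a multiple of 3")
    return TriangleMesh(vector.reshape(-1, 3), np.asarray(faces))


def _closest_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Distance from each point to its (n, k, 3, 3) candidate triangles.

    Vectorised closest-point-on-triangle via barycentric clamping
    (Ericson's region test).  Returns (n, k) distances.
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    p = points[:, None, :]
    ab, ac, ap = b - a, c - a, p - a
    d1 = (ab * ap).sum(-1)
    d2 = (ac * ap).sum(-1)
    bp = p - b
    d3 = (ab * bp).sum(-1)
    d4 = (ac * bp).sum(-1)
    cp = p - c
    d5 = (ab * cp).sum(-1)
    d6 = (ac * cp).sum(-1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    # interior barycentric coordinates (guard degenerate/zero denominators)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)

    u_ab = np.clip(np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0), 0.0, 1.0)
    u_ac = np.clip(np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0), 0.0, 1.0)
    u_bc = np.clip(np.where((d4 - d3) + (d5 - d6) != 0,
                            (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0), 0.0, 1.0)

    cond_a = (d1 <= 0) & (d2 <= 0)
    cond_b = (d3 >= 0) & (d4 <= d3)
    cond_c = (d6 >= 0) & (d5 <= d6)
    cond_ab = (~cond_a) & (~cond_b) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    cond_ac = (~cond_a) & (~cond_c) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    cond_bc = (~cond_b) & (~cond_c) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    close = a + v[..., None] * ab + w[..., None] * ac          # face interior
    close = np.where(cond_bc[..., None], b + u_bc[..., None] * (c - b), close)
    close = np.where(cond_ac[..., None], a + u_ac[..., None] * ac, close)
    close = np.where(cond_ab[..., None], a + u_ab[..., None] * ab, close)
    close = np.where(cond_c[..., None], c, close)
    close = np.where(cond_b[..., None], b, close)
    close = np.where(cond_a[..., None], a, close)
    return np.linalg.norm(p - close, axis=-1)


def surface_distance(query: TriangleMesh, reference: TriangleMesh,
                     n_candidates: int = 24) -> SurfaceDistanceMap:
    """Unsigned distance from each query vertex to the nearest point on the reference surface.

    Distances are point-to-triangle (interior, edge or vertex of the
    nearest face), not point-to-vertex, so coarse reference meshes do not
    bias the error upward.  Candidate faces per query point come from a
    KD-tree over face centroids plus the faces around the nearest
    reference vertex; exact distances are then taken over the candidates.
    """
    from scipy.spatial import cKDTree

    pts = query.vertices
    tris = reference.vertices[reference.faces]          # (m, 3, 3)
    centroids = tris.mean(axis=1)
    k = min(n_candidates, len(centroids))
    _, cand = cKDTree(centroids).query(pts, k=k)
    cand = np.atleast_2d(cand)
    if cand.shape[0] != len(pts):
        cand = cand.reshape(len(pts), -1)
    dist = _closest_on_triangles(pts, tris[cand]).min(axis=1)
    return SurfaceDistanceMap(dist)


def cranial_index(mesh: TriangleMesh) -> float:
    """Cranial index: 100 x maximum lateral width / maximum anteroposterior length.

    The mesh must sit in the anatomical frame used throughout the package:
    x lateral, y anteroposterior, z superior.  Both extents are
    axis-aligned bounding-box extents.
    """
    extent = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
    width, length = extent[0], extent[1]
    if length <= 0:
        raise ValueError("mesh has zero anteroposterior extent")
    return float(100.0 * width / length)


def mesh_volume(mesh: TriangleMesh, warn_open: bool = True) -> float:
    """Enclosed volume (mm^3) via the divergence theorem, as an absolute value.

    Open meshes yield a best-effort value; a warning is emitted because
    the divergence-theorem integral is only exact on closed surfaces.
    """
    tm = mesh.to_trimesh()
    if warn_open and not tm.is_watertight:
        import warnings

        warnings.warn("mesh is not watertight; volume is a best-effort estimate", stacklevel=2)
    return float(abs(tm.volume))


def offset_mesh(mesh: TriangleMesh, distance: float, direction: str = "outward") -> TriangleMesh:
    """Displace every vertex by ``distance`` along its (area-weighted) vertex normal.

    This is the uniform-thickness skin offset used to convert between
    skull and head surfaces: topology is preserved exactly, which keeps
    the point correspondence intact (a true Minkowski offset would not).
    """
    if distance < 0:
        raise ValueError("offset distance must be non-negative")
    if direction not in ("inward", "outward"):
        raise ValueError("direction must be 'inward' or 'outward'")
    normals = mesh.to_trimesh().vertex_normals
    sign = 1.0 if direction == "outward" else -1.0
    return mesh.with_vertices(mesh.vertices + sign * distance * normals)


def volume_match_scale(mesh: TriangleMesh, reference: TriangleMesh) -> TriangleMesh:
    """Uniformly scale ``mesh`` about its centroid so its volume matches ``reference``.

    Used to remove inter-scan growth under the unchanged-volume
    assumption before computing surface errors.
    """
    v_ref = mesh_volume(reference, warn_open=False)
    v_mesh = mesh_volume(mesh, warn_open=False)
    if v_ref <= 0:
        raise ValueError("reference mesh has zero volume")
    if v_mesh <= 0:
        raise ValueError("mesh has zero volume")
    s = (v_ref / v_mesh) ** (1.0 / 3.0)
    centroid = mesh.vertices.mean(axis=0)
    return mesh.with_vertices(centroid + s * (mesh.vertices - centroid))
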