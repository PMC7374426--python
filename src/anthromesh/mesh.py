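"""Triangle meshes: I/O, ray-triangle intersection, exact section/volume.

The mesh is the measurement substrate. Ray casting is the workhorse of the
girth/area/volume estimators; the exact plane-section and divergence-theorem
volume routines serve as ground-truth oracles for those estimators.

Conventions: centimeters, right-handed axes, y vertical.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import trimesh

from .transforms import RigidTransform

__all__ = [
    "TriangleMesh",
    "Ray",
    "Plane",
    "load_mesh",
    "save_mesh",
    "ray_first_hit",
    "ray_fan_first_hits",
    "exact_plane_section",
    "exact_mesh_volume",
]

log = logging.getLogger(__name__)

_UNIT_ATOL = 1e-9
_DEGENERATE_AREA = 1e-12


@dataclass(frozen=True)
class Ray:
    """Half-line from *origin* along unit *direction*."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        if abs(np.linalg.norm(d) - 1.0) > _UNIT_ATOL:
            raise ValueError("ray direction must be unit length")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class Plane:
    """Plane ``normal . x = offset`` with unit normal; offset in cm."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float).reshape(3)
        if abs(np.linalg.norm(n) - 1.0) > _UNIT_ATOL:
            raise ValueError("plane normal must be unit length")
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "offset", float(self.offset))

    @classmethod
    def from_point_normal(cls, point, normal) -> "Plane":
        n = np.asarray(normal, dtype=float)
        n = n / np.linalg.norm(n)
        return cls(n, float(n @ np.asarray(point, dtype=float)))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.normal - self.offset


class TriangleMesh:
    """Triangle surface mesh.

    Degenerate (zero-area) faces are dropped at construction and the count
    is logged. Vertex positions are stored as float64 cm.
    """

    def __init__(self, vertices, faces, vertex_normals: Optional[np.ndarray] = None):
        v = np.asarray(vertices, dtype=float).reshape(-1, 3)
        f = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of vertex range")
        areas = _triangle_areas(v, f)
        keep = areas > _DEGENERATE_AREA
        n_dropped = int((~keep).sum())
        if n_dropped:
            log.warning("dropped %d degenerate (zero-area) faces", n_dropped)
            f = f[keep]
        self.vertices = v
        self.faces = f
        self.vertex_normals = None
        if vertex_normals is not None:
            vn = np.asarray(vertex_normals, dtype=float).reshape(-1, 3)
            if vn.shape[0] != v.shape[0]:
                raise ValueError("vertex_normals length does not match vertices")
            self.vertex_normals = vn

    # -- basic geometry ----------------------------------------------
    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    @property
    def triangles(self) -> np.ndarray:
        """(n_faces, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self) -> np.ndarray:
        """Unit normals from winding order (right-hand rule)."""
        tri = self.triangles
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def bounds(self) -> np.ndarray:
        """(2, 3) min/max corner."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def transformed(self, T: RigidTransform) -> "TriangleMesh":
        vn = None if self.vertex_normals is None else T.apply_vectors(self.vertex_normals)
        return TriangleMesh(T.apply(self.vertices), self.faces, vn)

    def open_edge_count(self) -> int:
        """Number of edges bounding exactly one face (0 for watertight)."""
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return int((counts != 2).sum())

    def is_watertight(self) -> bool:
        return self.n_faces > 0 and self.open_edge_count() == 0

    # -- interop ------------------------------------------------------
    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))


def _triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = vertices[faces]
    return 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)


# ----------------------------------------------------------------------
# File I/O (PLY ascii/binary, OBJ) via trimesh.
# ----------------------------------------------------------------------

def load_mesh(path: str) -> TriangleMesh:
    """Load a PLY or OBJ triangle mesh; degenerate faces are dropped."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in (".ply", ".obj"):
        raise ValueError(f"unsupported mesh format: {ext!r} (use .ply or .obj)")
    try:
        tm = trimesh.load(path, force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot parse mesh file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValueError(f"mesh file {path} contains no triangle faces")
    return TriangleMesh.from_trimesh(tm)


def save_mesh(mesh: TriangleMesh, path: str) -> None:
    """Write PLY (ascii) or OBJ."""
    ext = os.path.splitext(path)[1].lower()
    if ext not in (".ply", ".obj"):
        raise ValueError(f"unsupported mesh format: {ext!r} (use .ply or .obj)")
    kwargs = {"encoding": "ascii"} if ext == ".ply" else {}
    mesh.to_trimesh().export(path, **kwargs)


# ----------------------------------------------------------------------
# Ray casting: vectorized Moller-Trumbore with an inclusive barycentric
# boundary (eps 1e-9) so rays grazing shared edges of axis-aligned faces
# still register; ties at equal distance resolve to the lowest face index.
# ----------------------------------------------------------------------

_BARY_EPS = 1e-9
_BLOCK_ELEMS = 4_000_000  # ray x face elements per block, bounds peak memory


def ray_fan_first_hits(
    mesh: TriangleMesh,
    origins: np.ndarray,
    directions: np.ndarray,
    face_subset: Optional[np.ndarray] = None,
):
    """First intersection of many rays with a mesh.

    Parameters
    ----------
    origins, directions : (n, 3)
        Ray origins and unit directions.
    face_subset : optional int array
        Restrict the test to these face indices (hit indices are still
        reported in the full mesh's numbering).

    Returns
    -------
    hit : (n,) bool mask
    points : (n, 3) hit coordinates (NaN where missed)
    face_index : (n,) int (-1 where missed)
    distance : (n,) float (inf where missed)
    """
    origins = np.asarray(origins, dtype=float).reshape(-1, 3)
    directions = np.asarray(directions, dtype=float).reshape(-1, 3)
    n = origins.shape[0]

    faces = mesh.faces if face_subset is None else mesh.faces[face_subset]
    face_ids = (np.arange(mesh.n_faces) if face_subset is None
                else np.asarray(face_subset, dtype=np.int64))
    tri = mesh.vertices[faces]
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0  # (F, 3)
    e2 = tri[:, 2] - v0

    best_t = np.full(n, np.inf)
    best_f = np.full(n, -1, dtype=np.int64)

    chunk = int(np.clip(_BLOCK_ELEMS // max(len(faces), 1), 16, 8192))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        O = origins[lo:hi, None, :]       # (B, 1, 3)
        D = directions[lo:hi, None, :]
        pvec = np.cross(D, e2[None, :, :])            # (B, F, 3)
        det = np.einsum("bfi,fi->bf", pvec, e1)
        ok = np.abs(det) > 1e-14
        inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = O - v0[None, :, :]
        u = np.einsum("bfi,bfi->bf", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("bfi,bfi->bf", qvec, D) * inv_det
        t = np.einsum("bfi,fi->bf", qvec, e2) * inv_det
        ok &= (u >= -_BARY_EPS) & (v >= -_BARY_EPS) & (u + v <= 1.0 + _BARY_EPS)
        ok &= t >= -_BARY_EPS
        t = np.where(ok, t, np.inf)
        # nearest hit; distance ties broken toward the lowest face index
        # (argmin returns the first minimum in storage order)
        j = np.argmin(t, axis=1)
        rows = np.arange(hi - lo)
        tmin = t[rows, j]
        hit_rows = np.isfinite(tmin)
        best_t[lo:hi][hit_rows] = np.maximum(tmin[hit_rows], 0.0)
        best_f[lo:hi][hit_rows] = face_ids[j[hit_rows]]

    hit = best_f >= 0
    points = np.full((n, 3), np.nan)
    points[hit] = origins[hit] + best_t[hit, None] * directions[hit]
    return hit, points, best_f, best_t


def ray_first_hit(mesh: TriangleMesh, ray: Ray):
    """First hit of a single ray, or ``None`` if the ray misses.

    Returns ``(point, face_index, distance)`` for the smallest non-negative
    hit distance.
    """
    if mesh.n_faces == 0:
        raise ValueError("mesh has no faces")
    hit, pts, fidx, dist = ray_fan_first_hits(mesh, ray.origin[None], ray.direction[None])
    if not hit[0]:
        return None
    return pts[0], int(fidx[0]), float(dist[0])


# ----------------------------------------------------------------------
# Exact oracles.
# ----------------------------------------------------------------------

def exact_plane_section(mesh: TriangleMesh, plane: Plane) -> list[np.ndarray]:
    """Exact cross-section of a mesh with a plane, as closed loops.

    Returns a list of (k, 3) vertex arrays, each a closed polyline (the
    closing edge from last back to first vertex is implicit), oriented
    counter-clockwise about the plane normal. An empty list means the
    plane misses the mesh; degenerate (near-zero-length) loops from
    tangent contact are suppressed.
    """
    tm = mesh.to_trimesh()
    origin = plane.normal * plane.offset
    try:
        path = tm.section(plane_origin=origin, plane_normal=plane.normal)
    except Exception:
        return []
    if path is None:
        return []
    loops: list[np.ndarray] = []
    for poly in path.discrete:
        pts = np.asarray(poly, dtype=float)
        closed = np.allclose(pts[0], pts[-1], atol=1e-9)
        if closed:
            pts = pts[:-1]
        if len(pts) < 3:
            continue
        seg = np.roll(pts, -1, axis=0) - pts
        if np.linalg.norm(seg, axis=1).sum() < 1e-9:
            continue
        # orient CCW about the plane normal via the signed area
        center = pts.mean(axis=0)
        cr = np.cross(pts - center, np.roll(pts, -1, axis=0) - center).sum(axis=0)
        if cr @ plane.normal < 0:
            pts = pts[::-1]
        loops.append(pts)
    return loops


def loop_length(loop: np.ndarray) -> float:
    """Length of a closed polyline given as (k, 3) vertices."""
    return float(np.linalg.norm(np.roll(loop, -1, axis=0) - loop, axis=1).sum())


def loop_area(loop: np.ndarray, normal: np.ndarray) -> float:
    """Planar polygon area of a closed loop about *normal*."""
    center = loop.mean(axis=0)
    cr = np.cross(loop - center, np.roll(loop, -1, axis=0) - center).sum(axis=0)
    return float(abs(cr @ np.asarray(normal)) / 2.0)


def exact_mesh_volume(mesh: TriangleMesh) -> float:
    """Volume (cm^3) of a watertight mesh by the divergence theorem.

    The signed tetrahedron sum is returned as an absolute value so the
    result is winding-convention independent; a non-watertight mesh is
    rejected with its open-edge count.
    """
    n_open = mesh.open_edge_count()
    if n_open or mesh.n_faces == 0:
        raise ValueError(f"mesh is not watertight: {n_open} open edges")
    tri = mesh.triangles
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
    return float(abs(signed))
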