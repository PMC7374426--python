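"""Girth, area and volume of mesh sections by coplanar ray casting.

A specialist-placed oriented circle defines the section to measure: rays
start on the circle, travel in-plane radially toward its center
(perpendicular to the local tangent), and their first mesh hits sample
the section contour. The closed polyline through the hits in angular
order gives the perimeter; fan triangulation of the hits around the
circle center (the pivot) gives the area; stacking per-slice areas times
a slice height h gives the volume of a cylinder-selected region.

The method is valid for sections that are star-shaped about the pivot —
in practice convex, which all body sections used are. A pivot outside
the hit polygon raises instead of returning a silently wrong number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .mesh import Plane, TriangleMesh, exact_plane_section, loop_length, ray_fan_first_hits

__all__ = [
    "SectionCircle",
    "MeasureCylinder",
    "PerimeterResult",
    "AreaResult",
    "VolumeResult",
    "place_circle",
    "place_cylinder",
    "measure_perimeter",
    "measure_area",
    "measure_volume",
]

AUTO_FIT_MARGIN = 1.2  # circle radius = margin * farthest contour point


@dataclass(frozen=True)
class SectionCircle:
    """Oriented measurement circle: rays orbit its circumference.

    ``phase_axis`` optionally pins the in-plane direction of the first
    ray; carrying it along when mesh and circle are rigidly moved
    together keeps the ray fan — and hence the estimate — exactly
    invariant. When absent a deterministic basis is derived from the
    normal.
    """

    center: np.ndarray
    normal: np.ndarray
    radius: float
    phase_axis: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        n = n / np.linalg.norm(n)
        if self.radius <= 0:
            raise ValueError("circle radius must be > 0")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "normal", n)
        if self.phase_axis is not None:
            u = np.asarray(self.phase_axis, dtype=float).reshape(3)
            u = u - (u @ n) * n  # project into the circle plane
            norm = np.linalg.norm(u)
            if norm < 1e-9:
                raise ValueError("phase_axis is parallel to the circle normal")
            object.__setattr__(self, "phase_axis", u / norm)

    def in_plane_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal (u, v) spanning the circle plane."""
        n = self.normal
        if self.phase_axis is not None:
            u = self.phase_axis
            return u, np.cross(n, u)
        a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(n, a)
        u = u / np.linalg.norm(u)
        return u, np.cross(n, u)


@dataclass(frozen=True)
class MeasureCylinder:
    """Volume selector: a circle swept along its normal over *height*,
    sliced every *slice_h* cm."""

    base: SectionCircle
    height: float
    slice_h: float = 1.0

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("cylinder height must be > 0")
        if not (0 < self.slice_h <= self.height):
            raise ValueError("slice height h must satisfy 0 < h <= height")


@dataclass(frozen=True)
class PerimeterResult:
    length: float
    hit_points: np.ndarray
    rays_cast: int
    rays_missed: int


@dataclass(frozen=True)
class AreaResult:
    area: float
    triangle_count: int
    pivot: np.ndarray


@dataclass(frozen=True)
class VolumeResult:
    volume: float
    slice_areas: list
    slice_heights: list
    slice_h: float
    empty_slices: list = field(default_factory=list)


# ----------------------------------------------------------------------
# Section selection.
# ----------------------------------------------------------------------

def place_circle(mesh: TriangleMesh, height: float, normal=(0.0, 1.0, 0.0)) -> SectionCircle:
    """Auto-fit a measurement circle around the section at *height*.

    The section plane has the given normal and passes through the point at
    *height* on the vertical line through the mesh centroid. The circle is
    centered on the largest section loop's centroid with radius 1.2x the
    farthest loop point, so the contour always lies inside the circle.
    """
    centroid = mesh.vertices.mean(axis=0)
    anchor = np.array([centroid[0], height, centroid[2]])
    plane = Plane.from_point_normal(anchor, normal)
    loops = exact_plane_section(mesh, plane)
    if not loops:
        raise ValueError(f"empty section: the plane at height {height} misses the mesh")
    loop = max(loops, key=loop_length)
    seg = np.roll(loop, -1, axis=0) - loop
    w = np.linalg.norm(seg, axis=1)
    mids = loop + 0.5 * seg
    center = (mids * w[:, None]).sum(axis=0) / w.sum()
    radius = AUTO_FIT_MARGIN * float(np.linalg.norm(loop - center, axis=1).max())
    return SectionCircle(center, plane.normal, radius)


def place_cylinder(mesh: TriangleMesh, slice_h: float = 1.0) -> MeasureCylinder:
    """Enclose the whole mesh in a vertical measurement cylinder."""
    lo, hi = mesh.bounds()
    centroid = mesh.vertices.mean(axis=0)
    center_xz = np.array([centroid[0], lo[1], centroid[2]])
    horiz = mesh.vertices[:, [0, 2]] - center_xz[[0, 2]]
    radius = AUTO_FIT_MARGIN * float(np.linalg.norm(horiz, axis=1).max())
    base = SectionCircle(center_xz, (0.0, 1.0, 0.0), radius)
    return MeasureCylinder(base, float(hi[1] - lo[1]), slice_h)


# ----------------------------------------------------------------------
# Ray-fan measurement.
# ----------------------------------------------------------------------

def _section_faces(mesh: TriangleMesh, circle: SectionCircle) -> np.ndarray:
    """Indices of faces that cross the circle's plane (the only ones an
    in-plane ray can hit transversally)."""
    d = mesh.vertices @ circle.normal - circle.normal @ circle.center
    df = d[mesh.faces]
    return np.flatnonzero((df.min(axis=1) <= 1e-9) & (df.max(axis=1) >= -1e-9))


_N_BINS = 256
_SPAN_PAD = 1e-6  # rad, guards float error at angular-span boundaries


def _fan_hits(mesh: TriangleMesh, circle: SectionCircle, n_rays: int):
    u, v = circle.in_plane_basis()
    theta = 2.0 * np.pi * np.arange(n_rays) / n_rays
    rim = np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v
    origins = circle.center + circle.radius * rim
    directions = -rim  # radially inward = perpendicular to the local tangent
    faces = _section_faces(mesh, circle)
    if len(faces) == 0:
        return np.zeros(n_rays, dtype=bool), np.empty((0, 3))
    if len(faces) <= 512:
        hit, pts, _, _ = ray_fan_first_hits(mesh, origins, directions, face_subset=faces)
        return hit, pts[hit]

    # Angular pruning: an in-plane radial ray at angle t can only meet a
    # face whose angular span about the circle center covers t or t + pi
    # (a hit past the center). Bucket faces by span, rays by angle.
    rel = mesh.vertices[mesh.faces[faces]] - circle.center   # (F, 3, 3)
    ang = np.arctan2(rel @ v, rel @ u)                        # (F, 3)
    ref = ang[:, :1]
    d = (ang - ref + np.pi) % (2 * np.pi) - np.pi
    lo = ref[:, 0] + d.min(axis=1) - _SPAN_PAD
    hi_ = ref[:, 0] + d.max(axis=1) + _SPAN_PAD
    wide = (d.max(axis=1) - d.min(axis=1)) > np.pi  # span ambiguous: test everywhere

    width = 2 * np.pi / _N_BINS
    bin_faces: list[list[int]] = [[] for _ in range(_N_BINS)]
    b_lo = np.floor(lo / width).astype(int)
    b_hi = np.floor(hi_ / width).astype(int)
    for i, fidx in enumerate(faces):
        if wide[i]:
            for b in range(_N_BINS):
                bin_faces[b].append(fidx)
        else:
            for b in range(b_lo[i], b_hi[i] + 1):
                bin_faces[b % _N_BINS].append(fidx)

    ray_bin = np.floor(theta / width).astype(int) % _N_BINS
    hit = np.zeros(n_rays, dtype=bool)
    pts = np.full((n_rays, 3), np.nan)
    for b in range(_N_BINS):
        rays = np.flatnonzero(ray_bin == b)
        cand = sorted(set(bin_faces[b]) | set(bin_faces[(b + _N_BINS // 2) % _N_BINS]))
        if len(rays) == 0 or not cand:
            continue
        h, p, _, _ = ray_fan_first_hits(mesh, origins[rays], directions[rays],
                                        face_subset=np.asarray(cand))
        hit[rays] = h
        pts[rays[h]] = p[h]
    return hit, pts[hit]


def measure_perimeter(mesh: TriangleMesh, circle: SectionCircle, n_rays: int = 10_000) -> PerimeterResult:
    """Section perimeter: closed polyline length through the ray hits.

    ``n_rays`` origins are equally spaced by angle on the circle and cast
    inward; hits are chained in angular order and the closing segment from
    the last hit back to the first is included. Missed rays are skipped.
    """
    if n_rays < 3:
        raise ValueError("need at least 3 rays")
    hit, pts = _fan_hits(mesh, circle, n_rays)
    if len(pts) < 3:
        raise ValueError("insufficient contour support: fewer than 3 rays hit the mesh")
    length = float(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1).sum())
    return PerimeterResult(length, pts, n_rays, int(n_rays - hit.sum()))


def measure_area(mesh: TriangleMesh, circle: SectionCircle, n_rays: int = 10_000) -> AreaResult:
    """Section area by fan triangulation of the ray hits about the pivot.

    The pivot is the circle center; consecutive hit pairs (closing pair
    included) form triangles with it whose areas are summed. Mixed
    triangle orientations mean the pivot falls outside the hit polygon,
    which breaks the fan decomposition and raises an error.
    """
    if n_rays < 3:
        raise ValueError("need at least 3 rays")
    _, pts = _fan_hits(mesh, circle, n_rays)
    if len(pts) < 3:
        raise ValueError("insufficient contour support: fewer than 3 rays hit the mesh")
    a = pts - circle.center
    b = np.roll(pts, -1, axis=0) - circle.center
    cross = np.cross(a, b)
    signed = cross @ circle.normal / 2.0
    scale = max(1.0, float(np.abs(signed).max()))
    if (signed > 1e-12 * scale).any() and (signed < -1e-12 * scale).any():
        raise ValueError("non-star-shaped about pivot: circle center lies outside the section")
    area = float(np.abs(signed.sum()))
    return AreaResult(area, len(pts), circle.center.copy())


def measure_volume(mesh: TriangleMesh, cyl: MeasureCylinder, n_rays: int = 10_000) -> VolumeResult:
    """Region volume by stacked slices.

    The cylinder is cut into slabs of height ``slice_h`` (the last slab
    keeps its true, possibly shorter, thickness); each slab contributes
    its mid-height section area times its thickness. Slabs whose section
    is empty contribute zero and are flagged; an all-empty cylinder is an
    error.
    """
    if n_rays < 3:
        raise ValueError("need at least 3 rays")
    h = cyl.slice_h
    edges = np.append(np.arange(0.0, cyl.height, h), cyl.height)
    areas: list[float] = []
    thicknesses: list[float] = []
    empty: list[int] = []
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        mid = 0.5 * (lo + hi)
        circle = SectionCircle(cyl.base.center + mid * cyl.base.normal,
                               cyl.base.normal, cyl.base.radius)
        try:
            areas.append(measure_area(mesh, circle, n_rays).area)
        except ValueError:
            areas.append(0.0)
            empty.append(i)
        thicknesses.append(float(hi - lo))
    if len(empty) == len(areas):
        raise ValueError("empty volume: no slice of the cylinder intersects the mesh")
    volume = float(np.dot(areas, thicknesses))
    return VolumeResult(volume, areas, thicknesses, h, empty)
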