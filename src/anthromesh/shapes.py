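"""Synthetic test objects and simulated RGB-D captures.

The shape generator produces the benchmark objects (cubes, cylinders, a
cone, a rectangular pyramid, a capsule body phantom) as watertight meshes
with the y-axis vertical and the base at height 0. The camera simulator
renders noisy depth point clouds of a scene through a pinhole model —
range noise is applied along the viewing ray, matching depth-sensor
physics — and drives the cube-marker calibration sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh

from .cloud import PointCloud
from .mesh import TriangleMesh, ray_fan_first_hits
from .transforms import RigidTransform

__all__ = [
    "ShapeSpec",
    "SimCamera",
    "make_shape",
    "make_cube",
    "render_depth_cloud",
    "simulate_marker_session",
    "camera_ring",
    "look_at_pose",
]

SHAPE_KINDS = ("cube", "cylinder", "cone", "rect_pyramid", "capsule_body")

# z-up (trimesh primitives) -> y-up (package convention)
_Z_TO_Y = RigidTransform.from_axis_angle([1, 0, 0], -np.pi / 2)


@dataclass(frozen=True)
class ShapeSpec:
    """Parametric description of a synthetic test object.

    dimensions (cm), per kind:
      cube:         side
      cylinder:     radius, height
      cone:         radius, height
      rect_pyramid: base_x, base_z, height
      capsule_body: radius, height (height of the cylindrical trunk)
    """

    kind: str
    dimensions: dict = field(default_factory=dict)
    tessellation: int = 4096

    def __post_init__(self) -> None:
        if self.kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}; choose from {SHAPE_KINDS}")
        if any(v <= 0 for v in self.dimensions.values()):
            raise ValueError("all dimensions must be positive")
        if self.tessellation < 16:
            raise ValueError("tessellation must be >= 16 facets")


def make_cube(side: float) -> TriangleMesh:
    """Axis-aligned cube of the given side, base at y=0, centered on the y-axis."""
    return make_shape(ShapeSpec("cube", {"side": side}))


def make_shape(spec: ShapeSpec) -> TriangleMesh:
    """Build a watertight mesh for *spec*, base at height 0, y vertical."""
    dims = spec.dimensions
    n = spec.tessellation
    if spec.kind == "cube":
        s = dims["side"]
        tm = trimesh.creation.box(extents=[s, s, s])
        tm.apply_translation([0, 0, s / 2])
    elif spec.kind == "cylinder":
        tm = trimesh.creation.cylinder(radius=dims["radius"], height=dims["height"], sections=n)
        tm.apply_translation([0, 0, dims["height"] / 2])
    elif spec.kind == "cone":
        tm = trimesh.creation.cone(radius=dims["radius"], height=dims["height"], sections=n)
    elif spec.kind == "rect_pyramid":
        return _rect_pyramid(dims["base_x"], dims["base_z"], dims["height"])
    elif spec.kind == "capsule_body":
        count = max(16, int(round(np.sqrt(n / 2))))
        tm = trimesh.creation.capsule(radius=dims["radius"], height=dims["height"],
                                      count=[count, count])
        tm.apply_translation([0, 0, dims["height"] / 2 + dims["radius"]])
    else:  # pragma: no cover - guarded by ShapeSpec
        raise ValueError(spec.kind)
    mesh = TriangleMesh.from_trimesh(tm).transformed(_Z_TO_Y)
    # snap the base exactly onto y=0 (rotation can leave ~1e-16 residue)
    mesh.vertices[:, 1] -= mesh.vertices[:, 1].min()
    return mesh


def make_prism(polygon: np.ndarray, height: float) -> TriangleMesh:
    """Extrude a convex CCW polygon (n, 2) in the xz-plane to a watertight
    prism of the given height, base at y=0."""
    poly = np.asarray(polygon, dtype=float).reshape(-1, 2)
    n = poly.shape[0]
    if n < 3:
        raise ValueError("polygon needs at least 3 vertices")
    bottom = np.column_stack([poly[:, 0], np.zeros(n), poly[:, 1]])
    top = bottom + [0.0, height, 0.0]
    vertices = np.vstack([bottom, top])
    faces = []
    for i in range(1, n - 1):  # caps: fan triangulation (convex)
        faces.append([0, i + 1, i])             # bottom, outward -y
        faces.append([n, n + i, n + i + 1])     # top, outward +y
    for i in range(n):  # sides
        j = (i + 1) % n
        faces.append([i, j, n + j])
        faces.append([i, n + j, n + i])
    mesh = TriangleMesh(vertices, faces)
    tri = mesh.triangles
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
    if signed < 0:
        mesh = TriangleMesh(vertices, np.asarray(faces)[:, ::-1])
    return mesh


def _rect_pyramid(bx: float, bz: float, h: float) -> TriangleMesh:
    hx, hz = bx / 2, bz / 2
    vertices = np.array([
        [-hx, 0, -hz], [hx, 0, -hz], [hx, 0, hz], [-hx, 0, hz],  # base
        [0, h, 0],                                                # apex
    ], dtype=float)
    faces = np.array([
        [0, 1, 2], [0, 2, 3],          # base (normal -y, outward)
        [1, 0, 4], [2, 1, 4], [3, 2, 4], [0, 3, 4],  # sides
    ])[:, ::-1]  # flip so outward normals follow the right-hand rule
    mesh = TriangleMesh(vertices, faces)
    # ensure outward orientation: signed volume must be positive
    tri = mesh.triangles
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
    if signed < 0:
        mesh = TriangleMesh(vertices, mesh.faces[:, ::-1])
    return mesh


# ----------------------------------------------------------------------
# Pinhole depth-camera simulation.
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SimCamera:
    """Pinhole RGB-D camera model for simulation.

    Camera frame: +z forward (depth axis), +x right, +y down (image
    rows). ``pose`` is camera-to-world. ``depth_sigma`` is the standard
    deviation (cm) of zero-mean Gaussian range noise applied along each
    viewing ray.
    """

    pose: RigidTransform
    focal_px: float = 200.0
    resolution: tuple = (128, 96)  # (width, height) px
    principal_px: Optional[tuple] = None  # defaults to image center
    depth_sigma: float = 0.0

    def __post_init__(self) -> None:
        w, h = self.resolution
        if w <= 0 or h <= 0:
            raise ValueError("resolution must be positive")
        if self.depth_sigma < 0:
            raise ValueError("depth noise sigma must be >= 0")

    def pixel_rays(self):
        """World-frame (origins, unit directions) for every pixel center."""
        w, h = self.resolution
        cx, cy = self.principal_px if self.principal_px is not None else ((w - 1) / 2, (h - 1) / 2)
        u, v = np.meshgrid(np.arange(w), np.arange(h))
        d_cam = np.column_stack([
            (u.ravel() - cx) / self.focal_px,
            (v.ravel() - cy) / self.focal_px,
            np.ones(w * h),
        ])
        d_cam /= np.linalg.norm(d_cam, axis=1, keepdims=True)
        d_world = self.pose.apply_vectors(d_cam)
        o_world = np.broadcast_to(self.pose.translation, d_world.shape)
        return o_world, d_world, d_cam


def render_depth_cloud(mesh: TriangleMesh, cam: SimCamera, seed: int = 0) -> PointCloud:
    """Simulate one depth capture of *mesh* (world frame) by *cam*.

    One point per pixel whose central ray hits the mesh, perturbed along
    the ray by Gaussian range noise of ``cam.depth_sigma``. The returned
    cloud is expressed in the **camera frame** (as a real sensor would
    deliver it); an all-miss view yields an empty cloud.
    """
    origins, dirs_world, dirs_cam = cam.pixel_rays()
    hit, _, _, dist = ray_fan_first_hits(mesh, origins, dirs_world)
    if not hit.any():
        return PointCloud(np.empty((0, 3)))
    t = dist[hit]
    if cam.depth_sigma > 0:
        rng = np.random.default_rng(seed)
        t = t + rng.normal(0.0, cam.depth_sigma, size=t.shape)
    return PointCloud(dirs_cam[hit] * t[:, None])


def look_at_pose(position, target, up=(0.0, 1.0, 0.0)) -> RigidTransform:
    """Camera-to-world pose with +z pointing from *position* to *target*."""
    p = np.asarray(position, dtype=float)
    z = np.asarray(target, dtype=float) - p
    z = z / np.linalg.norm(z)
    up = np.asarray(up, dtype=float)
    x = np.cross(z, up)
    nx = np.linalg.norm(x)
    if nx < 1e-9:  # looking straight along up: pick an arbitrary right vector
        x = np.cross(z, [1.0, 0.0, 0.0])
        nx = np.linalg.norm(x)
    x = x / nx
    y = np.cross(z, x)
    R = np.column_stack([x, y, z])
    return RigidTransform(R, p)


def camera_ring(
    n_cameras: int,
    radius: float,
    height: float,
    target=(0.0, 25.0, 0.0),
    focal_px: float = 200.0,
    resolution: tuple = (128, 96),
    depth_sigma: float = 0.0,
    phase: float = 0.0,
) -> list[SimCamera]:
    """Evenly spaced cameras on a horizontal circle, all looking at *target*."""
    cams = []
    for i in range(n_cameras):
        a = phase + 2 * np.pi * i / n_cameras
        pos = (radius * np.cos(a), height, radius * np.sin(a))
        cams.append(SimCamera(look_at_pose(pos, target), focal_px=focal_px,
                              resolution=resolution, depth_sigma=depth_sigma))
    return cams


def simulate_marker_session(
    cams: list[SimCamera],
    cube_edge: float,
    placements: list[RigidTransform],
    seed: int = 0,
):
    """Render a cube-marker calibration session.

    The marker is a cube of side ``cube_edge`` centered at the origin of
    its own frame; ``placements`` position it in the capture space. Each
    (camera, placement) pair yields one camera-frame cloud containing only
    marker-surface points visible to that camera (back faces are hidden by
    the first-hit rule). Per-capture noise streams are derived
    deterministically from *seed*.

    Returns
    -------
    clouds : dict[(cam_index, placement_index) -> PointCloud]
    empty : list of (cam_index, placement_index) pairs that saw nothing
    """
    if len(cams) < 2:
        raise ValueError("need at least 2 cameras")
    if len(placements) < 6:
        raise ValueError("need at least 6 marker placements")
    cube = make_cube(cube_edge)
    center_shift = RigidTransform(np.eye(3), [0.0, -cube_edge / 2, 0.0])
    clouds = {}
    empty = []
    ss = np.random.SeedSequence(seed)
    capture_seeds = ss.generate_state(len(cams) * len(placements)) % (2**31)
    for j, placement in enumerate(placements):
        world_cube = cube.transformed(placement @ center_shift)
        for i, cam in enumerate(cams):
            cloud = render_depth_cloud(world_cube, cam,
                                       seed=int(capture_seeds[j * len(cams) + i]))
            clouds[(i, j)] = cloud
            if len(cloud) == 0:
                empty.append((i, j))
    return clouds, empty
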