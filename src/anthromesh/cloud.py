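"""Point clouds with optional normals and colors, plus PLY/PCD I/O.

Clouds produced by a depth camera live in that camera's frame (origin at
the optical center, +z forward/depth). Units are centimeters.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import trimesh

from .transforms import RigidTransform

__all__ = ["PointCloud", "load_cloud", "save_cloud"]

_UNIT_ATOL = 1e-6


@dataclass
class PointCloud:
    """3D points with optional per-point unit normals and RGB colors."""

    points: np.ndarray
    normals: Optional[np.ndarray] = None
    colors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.normals is not None:
            n = np.asarray(self.normals, dtype=float).reshape(-1, 3)
            if n.shape[0] != self.points.shape[0]:
                raise ValueError("normals length does not match points")
            lens = np.linalg.norm(n, axis=1)
            if n.shape[0] and not np.allclose(lens, 1.0, atol=_UNIT_ATOL):
                raise ValueError("normals must be unit length within 1e-6")
            self.normals = n
        if self.colors is not None:
            c = np.asarray(self.colors)
            if c.shape[0] != self.points.shape[0]:
                raise ValueError("colors length does not match points")
            self.colors = c.reshape(-1, 3)

    def __len__(self) -> int:
        return self.points.shape[0]

    def select(self, mask_or_index) -> "PointCloud":
        """Subset cloud, carrying normals/colors along."""
        return PointCloud(
            self.points[mask_or_index],
            None if self.normals is None else self.normals[mask_or_index],
            None if self.colors is None else self.colors[mask_or_index],
        )

    def transformed(self, T: RigidTransform) -> "PointCloud":
        """Apply a rigid transform; normals are rotated only."""
        return PointCloud(
            T.apply(self.points),
            None if self.normals is None else T.apply_vectors(self.normals),
            self.colors,
        )


# ----------------------------------------------------------------------
# I/O. PLY goes through trimesh for reading; normals are written by our
# own ASCII emitter because trimesh does not round-trip point-cloud
# normals. PCD (ASCII) is read/written natively: no installed library
# handles the format.
# ----------------------------------------------------------------------

def save_cloud(cloud: PointCloud, path: str) -> None:
    """Write a cloud as ASCII PLY or PCD, chosen by file extension."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".ply":
        _write_ply(cloud, path)
    elif ext == ".pcd":
        _write_pcd(cloud, path)
    else:
        raise ValueError(f"unsupported point-cloud format: {ext!r} (use .ply or .pcd)")


def load_cloud(path: str) -> PointCloud:
    """Read a PLY or PCD point cloud."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".ply":
        return _read_ply(path)
    if ext == ".pcd":
        return _read_pcd(path)
    raise ValueError(f"unsupported point-cloud format: {ext!r} (use .ply or .pcd)")


def _write_ply(cloud: PointCloud, path: str) -> None:
    n = len(cloud)
    has_n = cloud.normals is not None
    has_c = cloud.colors is not None
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {n}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        if has_n:
            fh.write("property float nx\nproperty float ny\nproperty float nz\n")
        if has_c:
            fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        fh.write("end_header\n")
        for i in range(n):
            row = list(cloud.points[i])
            if has_n:
                row += list(cloud.normals[i])
            txt = " ".join(f"{v:.8g}" for v in row)
            if has_c:
                txt += " " + " ".join(str(int(v)) for v in cloud.colors[i])
            fh.write(txt + "\n")


def _read_ply(path: str) -> PointCloud:
    try:
        obj = trimesh.load(path, process=False)
    except Exception as exc:  # noqa: BLE001 - surface parse failures uniformly
        raise ValueError(f"cannot parse PLY file {path}: {exc}") from exc
    data = getattr(obj, "metadata", {}).get("_ply_raw", {}).get("vertex", {}).get("data")
    points = np.asarray(obj.vertices, dtype=float)
    normals = colors = None
    if data is not None:
        # trimesh exposes vertex properties as a structured array or a dict
        if isinstance(data, dict):
            fields = {k: np.asarray(v).ravel() for k, v in data.items()}
        elif data.dtype.names:
            fields = {k: data[k] for k in data.dtype.names}
        else:
            fields = {}
        if {"nx", "ny", "nz"} <= set(fields):
            normals = np.column_stack([fields["nx"], fields["ny"], fields["nz"]]).astype(float)
            lens = np.linalg.norm(normals, axis=1)
            lens[lens == 0] = 1.0
            normals = normals / lens[:, None]
        if {"red", "green", "blue"} <= set(fields):
            colors = np.column_stack([fields["red"], fields["green"], fields["blue"]])
    return PointCloud(points, normals, colors)


def _write_pcd(cloud: PointCloud, path: str) -> None:
    n = len(cloud)
    fields = ["x", "y", "z"]
    cols = [cloud.points]
    if cloud.normals is not None:
        fields += ["normal_x", "normal_y", "normal_z"]
        cols.append(cloud.normals)
    data = np.hstack(cols)
    with open(path, "w") as fh:
        fh.write("# .PCD v0.7 - Point Cloud Data file format\n")
        fh.write("VERSION 0.7\n")
        fh.write("FIELDS " + " ".join(fields) + "\n")
        fh.write("SIZE " + " ".join(["4"] * len(fields)) + "\n")
        fh.write("TYPE " + " ".join(["F"] * len(fields)) + "\n")
        fh.write("COUNT " + " ".join(["1"] * len(fields)) + "\n")
        fh.write(f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\nDATA ascii\n")
        for row in data:
            fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")


def _read_pcd(path: str) -> PointCloud:
    fields: list[str] = []
    n_points = None
    rows: list[list[float]] = []
    with open(path) as fh:
        in_data = False
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if in_data:
                rows.append([float(v) for v in line.split()])
                continue
            key, *rest = line.split()
            key = key.upper()
            if key == "FIELDS":
                fields = rest
            elif key == "POINTS":
                n_points = int(rest[0])
            elif key == "DATA":
                if rest[0].lower() != "ascii":
                    raise ValueError(f"only ASCII PCD supported, got {rest[0]!r}")
                in_data = True
    if not fields or not {"x", "y", "z"} <= set(fields):
        raise ValueError(f"PCD file {path} lacks x/y/z fields")
    arr = np.asarray(rows, dtype=float).reshape(-1, len(fields))
    if n_points is not None and arr.shape[0] != n_points:
        raise ValueError(f"PCD file {path}: POINTS={n_points} but {arr.shape[0]} rows")
    idx = {f: i for i, f in enumerate(fields)}
    points = arr[:, [idx["x"], idx["y"], idx["z"]]]
    normals = None
    if {"normal_x", "normal_y", "normal_z"} <= set(fields):
        normals = arr[:, [idx["normal_x"], idx["normal_y"], idx["normal_z"]]]
        lens = np.linalg.norm(normals, axis=1)
        lens[lens == 0] = 1.0
        normals = normals / lens[:, None]
    return PointCloud(points, normals)
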