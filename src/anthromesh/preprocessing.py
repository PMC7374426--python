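"""Point-cloud improvement chain and multi-view fusion.

Stages, in the order they are applied by :func:`preprocess`:

1. depth truncation (drop points beyond ``z_max`` along the camera z axis)
2. median filter on k-NN neighborhoods
3. bilateral filter (normal-displacement formulation)
4. statistical outlier removal (SOR)
5. normal estimation (PCA of the k-NN covariance, oriented to the camera)

Clouds are unorganized, so every neighborhood filter is defined on k
nearest neighbors via a KD-tree rather than on an image grid.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .transforms import RigidTransform

__all__ = [
    "FilterConfig",
    "truncate_depth",
    "median_filter",
    "bilateral_filter",
    "sor_filter",
    "estimate_normals",
    "fuse_clouds",
    "preprocess",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the preprocessing chain (lengths in cm)."""

    z_max: float = 100.0
    median_k: int = 9
    bilateral_sigma_s: float = 1.0
    bilateral_sigma_r: float = 0.5
    sor_k: int = 8
    sor_std_mult: float = 1.0
    normals_k: int = 16

    def __post_init__(self) -> None:
        if min(self.median_k, self.sor_k, self.normals_k) < 1:
            raise ValueError("neighbor counts must be >= 1")
        if min(self.bilateral_sigma_s, self.bilateral_sigma_r) <= 0:
            raise ValueError("bilateral sigmas must be > 0")
        if self.z_max <= 0:
            raise ValueError("z_max must be > 0")


def truncate_depth(cloud: PointCloud, z_max: float) -> PointCloud:
    """Drop points with camera-frame depth (z) beyond ``z_max``; order kept."""
    if z_max <= 0:
        raise ValueError("z_max must be > 0")
    return cloud.select(cloud.points[:, 2] <= z_max)


def median_filter(cloud: PointCloud, k: int = 9) -> PointCloud:
    """Replace each point by the component-wise median of its k nearest
    neighbors (the point itself included)."""
    n = len(cloud)
    if k > n:
        raise ValueError(f"median window k={k} exceeds cloud size {n}")
    tree = cKDTree(cloud.points)
    _, idx = tree.query(cloud.points, k=k)
    idx = np.atleast_2d(idx.reshape(n, -1))
    smoothed = np.median(cloud.points[idx], axis=1)
    return PointCloud(smoothed, cloud.normals, cloud.colors)


def bilateral_filter(
    cloud: PointCloud,
    sigma_s: float = 1.0,
    sigma_r: float = 0.5,
    k: int = 16,
    camera_origin=(0.0, 0.0, 0.0),
) -> PointCloud:
    """Edge-preserving smoothing by displacement along the point normal.

    Each point moves along its normal by the average of its neighbors'
    normal-projected offsets, weighted spatially (Gaussian, ``sigma_s``)
    and by the offset magnitude itself (range Gaussian, ``sigma_r``).
    Normals are estimated on the fly when the cloud has none.
    """
    n = len(cloud)
    if k > n:
        raise ValueError(f"bilateral neighborhood k={k} exceeds cloud size {n}")
    work = cloud if cloud.normals is not None else estimate_normals(cloud, min(k, n), camera_origin)
    tree = cKDTree(work.points)
    dist, idx = tree.query(work.points, k=k)
    dist = np.atleast_2d(dist.reshape(n, -1))
    idx = np.atleast_2d(idx.reshape(n, -1))
    offsets = work.points[idx] - work.points[:, None, :]          # (n, k, 3)
    d_normal = np.einsum("nkj,nj->nk", offsets, work.normals)      # signed offsets
    w = np.exp(-0.5 * (dist / sigma_s) ** 2) * np.exp(-0.5 * (d_normal / sigma_r) ** 2)
    disp = (w * d_normal).sum(axis=1) / w.sum(axis=1)
    moved = work.points + disp[:, None] * work.normals
    return PointCloud(moved, work.normals, cloud.colors)


def sor_filter(cloud: PointCloud, k: int = 8, std_mult: float = 1.0) -> PointCloud:
    """Statistical outlier removal.

    A point is discarded when its mean distance to its k nearest
    neighbors exceeds (global mean + ``std_mult`` * global std) of that
    statistic. The output is always a subset of the input.
    """
    n = len(cloud)
    if k + 1 > n:
        raise ValueError(f"SOR neighborhood k={k} requires more than k+1 points (have {n})")
    tree = cKDTree(cloud.points)
    dist, _ = tree.query(cloud.points, k=k + 1)  # first neighbor is the point itself
    mean_d = dist[:, 1:].mean(axis=1)
    keep = mean_d <= mean_d.mean() + std_mult * mean_d.std()
    return cloud.select(keep)


def estimate_normals(cloud: PointCloud, k: int = 16, camera_origin=(0.0, 0.0, 0.0)) -> PointCloud:
    """Per-point unit normals from local PCA.

    The normal is the smallest-eigenvalue eigenvector of the k-NN
    covariance, sign-oriented toward ``camera_origin`` (a sensor only sees
    surfaces facing it).
    """
    n = len(cloud)
    if k < 3:
        raise ValueError("normal estimation needs k >= 3")
    if n < k:
        raise ValueError(f"normal estimation needs at least k={k} points (have {n})")
    tree = cKDTree(cloud.points)
    _, idx = tree.query(cloud.points, k=k)
    nbrs = cloud.points[idx]                      # (n, k, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / k
    _, vecs = np.linalg.eigh(cov)                 # ascending eigenvalues
    normals = vecs[:, :, 0]
    to_cam = np.asarray(camera_origin, dtype=float) - cloud.points
    flip = np.einsum("ni,ni->n", normals, to_cam) < 0
    normals[flip] *= -1.0
    return PointCloud(cloud.points, normals, cloud.colors)


def fuse_clouds(clouds: list[PointCloud], transforms: list[RigidTransform]) -> PointCloud:
    """Concatenate per-camera clouds in the reference frame.

    ``transforms[i]`` maps camera *i* into the reference frame; the
    reference camera's entry must be the identity. Normals are rotated,
    never translated.
    """
    if len(clouds) != len(transforms):
        raise ValueError(f"{len(clouds)} clouds but {len(transforms)} transforms")
    if not any(np.allclose(T.matrix, np.eye(4), atol=1e-9) for T in transforms):
        raise ValueError("one transform must be the identity (the reference camera)")
    moved = [c.transformed(T) for c, T in zip(clouds, transforms)]
    points = np.vstack([c.points for c in moved])
    normals = None
    if all(c.normals is not None for c in moved) and moved:
        normals = np.vstack([c.normals for c in moved])
    colors = None
    if all(c.colors is not None for c in moved) and moved:
        colors = np.vstack([c.colors for c in moved])
    return PointCloud(points, normals, colors)


def preprocess(cloud: PointCloud, config: FilterConfig = FilterConfig()) -> PointCloud:
    """Run the full chain: truncate, median, bilateral, SOR, normals."""
    stages = [
        ("truncate", lambda c: truncate_depth(c, config.z_max)),
        ("median", lambda c: median_filter(c, config.median_k)),
        ("bilateral", lambda c: bilateral_filter(c, config.bilateral_sigma_s,
                                                 config.bilateral_sigma_r)),
        ("sor", lambda c: sor_filter(c, config.sor_k, config.sor_std_mult)),
        ("normals", lambda c: estimate_normals(c, config.normals_k)),
    ]
    for name, fn in stages:
        before = len(cloud)
        cloud = fn(cloud)
        log.info("preprocess %-9s %d -> %d points", name, before, len(cloud))
    return cloud
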