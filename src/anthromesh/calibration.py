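"""Extrinsic multi-camera calibration from cube-marker captures.

A cube of known edge length is placed at several positions in the capture
space and seen by every camera. Each capture is fitted with up to three
mutually orthogonal planes (cluster / regress / reassign), the cube center
is recovered from the fitted patches, and the per-placement centers give
point correspondences between cameras. Robust rigid alignment
(RANSAC-wrapped Procrustes) chains the cameras of each row together and
then aligns the rows through cameras sharing a mast, producing one
transform per camera into the reference camera's frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np

from .cloud import PointCloud
from .mesh import Plane
from .preprocessing import estimate_normals
from .transforms import RigidTransform

__all__ = [
    "CubeModel",
    "MarkerObservation",
    "CalibrationResult",
    "fit_cube_faces",
    "cube_center",
    "procrustes",
    "ransac_align",
    "calibrate_network",
]

log = logging.getLogger(__name__)

_MERGE_ANGLE_RAD = np.deg2rad(25.0)  # normal modes closer than this are one face


@dataclass
class CubeModel:
    """1-3 mutually orthogonal planar patches fitted to a marker capture.

    Plane normals are oriented outward, i.e. toward the observing camera.
    ``labels`` assigns every retained point to a plane; ``residual`` is the
    RMS point-to-assigned-plane distance in cm.
    """

    planes: list
    labels: np.ndarray
    residual: float
    valid: bool
    points: np.ndarray = field(repr=False, default=None)
    camera_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    residual_history: list = field(default_factory=list, repr=False)

    @property
    def n_planes(self) -> int:
        return len(self.planes)


@dataclass
class MarkerObservation:
    """One (camera, placement) marker capture, with fit products."""

    camera: object
    placement: object
    cloud: Optional[PointCloud] = None
    model: Optional[CubeModel] = None
    center: Optional[np.ndarray] = None


@dataclass
class CalibrationResult:
    """Per-camera rigid transforms into the reference camera's frame."""

    transforms: dict
    reference: object
    inlier_placements: dict
    rms: dict
    uncalibrated: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# Cube-face fitting: cluster normals, fit an orthogonal frame, reassign.
# ----------------------------------------------------------------------

def _spherical_kmeans(normals: np.ndarray, max_k: int):
    """Cluster unit normals into <= max_k directional modes.

    Deterministic farthest-first seeding followed by spherical k-means;
    seed centers closer than the merge angle collapse, so a single-face
    cloud yields a single cluster. Returns (labels, centers).
    """
    centers = [normals.mean(axis=0)]
    centers[0] = centers[0] / np.linalg.norm(centers[0])
    cos_merge = np.cos(_MERGE_ANGLE_RAD)
    for _ in range(max_k - 1):
        best = np.max(np.column_stack([normals @ c for c in centers]), axis=1)
        i = int(np.argmin(best))
        if best[i] >= cos_merge:
            break  # no further mode separated enough
        centers.append(normals[i])
    C = np.vstack(centers)
    for _ in range(20):
        labels = np.argmax(normals @ C.T, axis=1)
        newC = []
        for k in range(C.shape[0]):
            sel = labels == k
            if not sel.any():
                continue
            m = normals[sel].mean(axis=0)
            newC.append(m / np.linalg.norm(m))
        newC = np.vstack(newC)
        if newC.shape == C.shape and np.allclose(newC, C, atol=1e-9):
            C = newC
            break
        C = newC
    labels = np.argmax(normals @ C.T, axis=1)
    return labels, C


def _orthogonal_frame(cluster_normals: np.ndarray) -> np.ndarray:
    """Project 2-3 approximate face normals onto the nearest orthonormal
    frame (polar decomposition); returns a (k, 3) row-per-axis array."""
    k = cluster_normals.shape[0]
    N = cluster_normals.T.copy()  # columns are normals
    if k == 2:
        third = np.cross(N[:, 0], N[:, 1])
        N = np.column_stack([N, third / np.linalg.norm(third)])
    U, _, Vt = np.linalg.svd(N)
    Q = U @ Vt  # nearest orthogonal matrix in Frobenius norm
    return Q.T[:k]


def _fit_planes(points: np.ndarray, labels: np.ndarray, k: int,
                camera_origin: np.ndarray) -> list:
    """Per-cluster PCA normals, joint orthogonalization, mean offsets."""
    raw = []
    for i in range(k):
        pts = points[labels == i]
        c = pts.mean(axis=0)
        cov = (pts - c).T @ (pts - c)
        _, vecs = np.linalg.eigh(cov)
        n = vecs[:, 0]
        if n @ (camera_origin - c) < 0:
            n = -n
        raw.append(n)
    axes = np.vstack(raw) if k == 1 else _orthogonal_frame(np.vstack(raw))
    planes = []
    for i in range(k):
        q = axes[i] / np.linalg.norm(axes[i])
        pts = points[labels == i]
        if q @ (camera_origin - pts.mean(axis=0)) < 0:
            q = -q
        planes.append(Plane(q, float((pts @ q).mean())))
    return planes


def _ransac_plane_init(points: np.ndarray, max_planes: int, rng: np.random.Generator,
                       tol: float = 0.5, iters: int = 120):
    """Sequential RANSAC plane extraction as a clustering initializer.

    Greedily finds up to ``max_planes`` dominant planes by 3-point
    sampling, peeling off inliers after each find. Robust to the blended
    point normals near cube edges that can mislead the normal-space
    clustering. Returns a label array (every point assigned to its
    nearest found plane) or None if no plane is supported.
    """
    n = len(points)
    remaining = np.arange(n)
    plane_list = []
    for _ in range(max_planes):
        if len(remaining) < 30:
            break
        pts = points[remaining]
        best = None
        for _ in range(iters):
            i3 = rng.choice(len(pts), size=3, replace=False)
            a, b, c = pts[i3]
            nv = np.cross(b - a, c - a)
            norm = np.linalg.norm(nv)
            if norm < 1e-9:
                continue
            nv = nv / norm
            d = np.abs(pts @ nv - nv @ a)
            count = int((d < tol).sum())
            if best is None or count > best[0]:
                best = (count, nv, float(nv @ a))
        if best is None or best[0] < max(30, int(0.05 * n)):
            break
        nv, dv = best[1], best[2]
        for _ in range(3):  # PCA refinement on the consensus set
            sel = np.abs(pts @ nv - dv) < tol
            ip = pts[sel]
            cen = ip.mean(axis=0)
            _, vecs = np.linalg.eigh((ip - cen).T @ (ip - cen))
            nv = vecs[:, 0]
            dv = float(nv @ cen)
        plane_list.append((nv, dv))
        keep = np.abs(pts @ nv - dv) >= tol
        remaining = remaining[keep]
    if not plane_list:
        return None
    D = np.abs(np.column_stack([points @ nv - dv for nv, dv in plane_list]))
    return np.argmin(D, axis=1)


def _drop_weak_clusters(points: np.ndarray, labels: np.ndarray, k: int):
    """Remove clusters that cannot support a plane fit: too few points
    (under 2% of the cloud or 5 absolute) or nearly collinear ones, whose
    PCA normal is unconstrained (edge slivers between two faces). Their
    points are reabsorbed by the nearest surviving plane on reassignment.
    """
    n = len(points)
    min_pts = max(5, int(0.02 * n))
    keep = []
    for i in range(k):
        pts = points[labels == i]
        if len(pts) < min_pts:
            keep.append(False)
            continue
        sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        keep.append(sv[1] > max(1e-9, 0.02 * sv[0]))
    keep = np.asarray(keep, dtype=bool)
    if keep.all():
        return labels, k
    if not keep.any():
        return labels, 0
    remap = np.maximum(np.cumsum(keep) - 1, 0)
    # dropped points temporarily join the first kept cluster; the next
    # reassignment step re-homes them by distance
    new_labels = np.where(keep[labels], remap[labels], 0)
    return new_labels, int(keep.sum())


def _plane_distances(points: np.ndarray, planes: list) -> np.ndarray:
    """(n, k) absolute point-to-plane distances."""
    return np.abs(np.column_stack([p.signed_distance(points) for p in planes]))


def _iterate_fit(points, labels, cam, max_iter):
    """Alternate orthogonality-constrained regression and nearest-plane
    reassignment from an initial labeling. Keeps the best (lowest-residual)
    state, so the returned residual history is non-increasing.

    A fitted plane is discarded mid-loop when most of its points are
    already explained by the other planes (an edge band between two faces
    masquerading as a third patch) or when its cluster degenerates.
    Returns (planes, labels, residual, history) or None.
    """
    n = len(points)
    k = int(labels.max()) + 1
    best = None
    history: list[float] = []
    for _ in range(max_iter):
        labels, k = _drop_weak_clusters(points, labels, k)
        if k == 0:
            return None
        planes = _fit_planes(points, labels, k, cam)
        d = _plane_distances(points, planes)
        new_labels = np.argmin(d, axis=1)
        assigned = d[np.arange(n), new_labels]
        residual = float(np.sqrt((assigned ** 2).mean()))
        # redundancy test: drop a plane whose points mostly lie on another
        if k > 1:
            near_tol = max(0.3, 2.0 * residual)
            dropped = False
            for i in range(k):
                sel = new_labels == i
                if not sel.any():
                    continue
                others = np.delete(d[sel], i, axis=1).min(axis=1)
                if (others < near_tol).mean() > 0.7:
                    keep = np.ones(k, dtype=bool)
                    keep[i] = False
                    new_labels = np.argmin(d[:, keep], axis=1)
                    k -= 1
                    dropped = True
                    break
            if dropped:
                labels = new_labels
                continue
        if best is None or residual < best[2]:
            best = (planes, new_labels.copy(), residual)
            history.append(residual)
        changed = int((new_labels != labels).sum())
        labels = new_labels
        if changed <= int(0.001 * n):
            break
    if best is None:
        return None
    planes, labels, residual = best
    polished = _trimmed_polish(points, planes, labels, cam)
    if polished is not None and polished[2] <= residual:
        planes, labels, residual = polished
        history.append(residual)
    return planes, labels, residual, history


def _trimmed_polish(points, planes, labels, cam):
    """Refit the converged planes on their well-explained points only.

    Stragglers — grazing slivers of a barely visible third face, or noise
    tails — sit far from every fitted plane and bias the final regression;
    one trimmed refit restores exact plane parameters on clean data.
    """
    k = len(planes)
    d = _plane_distances(points, planes)
    assigned = d[np.arange(len(points)), labels]
    cut = max(5.0 * float(np.median(assigned)), 1e-12)
    keep = assigned <= cut
    if keep.sum() < 30:
        return None
    sub_labels = labels[keep]
    if np.bincount(sub_labels, minlength=k).min() < 3:
        return None
    planes2 = _fit_planes(points[keep], sub_labels, k, cam)
    d2 = _plane_distances(points, planes2)
    labels2 = np.argmin(d2, axis=1)
    assigned2 = d2[np.arange(len(points)), labels2]
    kept2 = assigned2 <= max(5.0 * float(np.median(assigned2)), 1e-12)
    residual2 = float(np.sqrt((assigned2[kept2] ** 2).mean()))
    return planes2, labels2, residual2


def fit_cube_faces(
    cloud: PointCloud,
    max_planes: int = 3,
    camera_origin=(0.0, 0.0, 0.0),
    min_cluster: int = 10,
    residual_threshold: float = 1.0,
    normals_k: int = 16,
    max_iter: int = 50,
    seed: int = 0,
) -> CubeModel:
    """Fit up to three mutually orthogonal planes to a marker capture.

    Several initial clusterings are tried — spherical k-means on the
    point normals at every candidate plane count, plus a sequential
    RANSAC plane extraction — and each is refined by the alternating
    regression / reassignment loop; the lowest-residual converged model
    wins (more planes preferred on near-ties, since corner views
    constrain the cube center best). The model is flagged invalid — never
    raised — when the cloud is too small, a cluster starves
    (< ``min_cluster`` points), or the residual exceeds
    ``residual_threshold`` cm.
    """
    cam = np.asarray(camera_origin, dtype=float)
    points = cloud.points
    if len(points) < 30:
        return CubeModel([], np.empty(0, dtype=int), np.inf, False, points, cam)
    work = cloud if cloud.normals is not None else estimate_normals(
        cloud, min(normals_k, len(points)), camera_origin)
    labels0, centers = _spherical_kmeans(work.normals, max_planes)
    k0 = centers.shape[0]
    mode_order = np.argsort(-np.bincount(labels0, minlength=k0))  # by size

    inits = []
    for k_try in range(k0, 0, -1):
        kept = mode_order[:k_try]
        inits.append(np.argmax(work.normals @ centers[kept].T, axis=1))
    ransac_labels = _ransac_plane_init(points, max_planes, np.random.default_rng(seed))
    if ransac_labels is not None:
        inits.append(ransac_labels)

    candidates = []
    for sub in inits:
        fit = _iterate_fit(points, sub, cam, max_iter)
        if fit is None:
            continue
        planes, labels, residual, history = fit
        counts = np.bincount(labels, minlength=len(planes))
        valid = bool(len(planes) > 0 and counts.min() >= min_cluster
                     and residual <= residual_threshold)
        candidates.append(CubeModel(planes, labels, residual, valid, points, cam, history))
    if not candidates:
        return CubeModel([], np.empty(0, dtype=int), np.inf, False, points, cam)
    valid_ones = [m for m in candidates if m.valid]
    pool = valid_ones or candidates
    best_res = min(m.residual for m in pool)
    near = [m for m in pool if m.residual <= best_res * 1.05 + 1e-12]
    return max(near, key=lambda m: m.n_planes)


def cube_center(model: CubeModel, edge: float) -> np.ndarray:
    """Cube center from the fitted patches and the known edge length.

    3 planes: the visible-corner intersection stepped edge/2 inward along
    each face normal. 2 planes: the shared-edge midpoint (from the point
    extent along the edge) stepped inward twice. 1 plane: the patch
    center from in-plane extent midpoints, stepped inward once.

    The extent-based (1- and 2-plane) estimates are only correct when the
    supporting faces are fully visible — a face clipped by the image
    border biases the midpoint — so an extent inconsistent with the known
    edge length raises ``ValueError``.
    """
    if not model.valid:
        raise ValueError("cannot compute the center of an invalid cube model")
    e2 = edge / 2.0
    normals = np.vstack([p.normal for p in model.planes])  # outward (toward camera)
    offsets = np.array([p.offset for p in model.planes])
    if model.n_planes == 3:
        corner = np.linalg.solve(normals, offsets)
        return corner - e2 * normals.sum(axis=0)

    def _check_extent(span, what):
        if not (0.8 * edge <= span <= 1.25 * edge):
            raise ValueError(
                f"partial face visibility: {what} extent {span:.1f} cm is "
                f"inconsistent with the {edge:.1f} cm marker edge")

    if model.n_planes == 2:
        u = np.cross(normals[0], normals[1])
        u = u / np.linalg.norm(u)
        # minimal-norm point on the intersection line
        x0, *_ = np.linalg.lstsq(normals, offsets, rcond=None)
        t = model.points @ u
        _check_extent(float(t.max() - t.min()), "shared-edge")
        t_mid = 0.5 * (t.min() + t.max())
        edge_mid = x0 + (t_mid - x0 @ u) * u
        return edge_mid - e2 * normals.sum(axis=0)
    # single patch: face center from in-plane extent midpoints (exact for a
    # fully visible square face under any sampling density), one inward step
    q, d = normals[0], offsets[0]
    a = np.array([1.0, 0.0, 0.0]) if abs(q[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(q, a)
    u = u / np.linalg.norm(u)
    v = np.cross(q, u)
    tu, tv = model.points @ u, model.points @ v
    # a square face can sit diagonally in the (u, v) frame: check the
    # rotation-invariant bounds sqrt(area) <= span <= edge * sqrt(2)
    for span in (float(tu.max() - tu.min()), float(tv.max() - tv.min())):
        if not (0.8 * edge <= span <= 1.25 * np.sqrt(2) * edge):
            raise ValueError(
                f"partial face visibility: patch extent {span:.1f} cm is "
                f"inconsistent with the {edge:.1f} cm marker edge")
    c_on = (d * q + 0.5 * (tu.min() + tu.max()) * u + 0.5 * (tv.min() + tv.max()) * v)
    return c_on - e2 * q


# ----------------------------------------------------------------------
# Rigid alignment.
# ----------------------------------------------------------------------

def procrustes(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid alignment ``T`` minimizing ``sum |T(src) - dst|^2``.

    Closed-form Kabsch solution (SVD of the cross-covariance) with the
    reflection corrected to a proper rotation. Requires >= 3 pairs that
    are neither coincident nor collinear.
    """
    src = np.asarray(src, dtype=float).reshape(-1, 3)
    dst = np.asarray(dst, dtype=float).reshape(-1, 3)
    if src.shape != dst.shape or src.shape[0] < 3:
        raise ValueError("need >= 3 paired points of equal count")
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    A = src - cs
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[1] <= max(1e-9, 1e-9 * sv[0]):
        raise ValueError("source points are collinear or coincident; rotation is unconstrained")
    H = A.T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cd - R @ cs)


def ransac_align(
    src: np.ndarray,
    dst: np.ndarray,
    inlier_tol: float = 1.0,
    iters: int = 1000,
    seed: int = 0,
    src_normals: Optional[np.ndarray] = None,
    dst_normals: Optional[np.ndarray] = None,
):
    """RANSAC-wrapped Procrustes alignment of paired 3D points.

    Minimal 3-point models are drawn (exhaustively when the number of
    3-subsets fits in ``iters``, otherwise uniformly with the given seed);
    each is scored by consensus size, then by mean inlier distance — plus
    a mean normal-disagreement angle term when paired patch normals are
    supplied. The winning model is refitted on its inliers.

    Returns ``(RigidTransform, inlier index array)``; raises if no model
    reaches 3 inliers.
    """
    src = np.asarray(src, dtype=float).reshape(-1, 3)
    dst = np.asarray(dst, dtype=float).reshape(-1, 3)
    n = src.shape[0]
    if n < 4 or dst.shape[0] != n:
        raise ValueError("RANSAC alignment needs >= 4 paired points")
    all_triples = list(combinations(range(n), 3))
    if len(all_triples) <= iters:
        samples = all_triples
    else:
        rng = np.random.default_rng(seed)
        samples = [tuple(rng.choice(n, size=3, replace=False)) for _ in range(iters)]

    def _score(T: RigidTransform):
        d = np.linalg.norm(T.apply(src) - dst, axis=1)
        inl = np.flatnonzero(d <= inlier_tol)
        if len(inl) < 3:
            return None
        cost = float(d[inl].mean())
        if src_normals is not None and dst_normals is not None:
            rs = T.apply_vectors(src_normals[inl])
            cosang = np.clip(np.einsum("ij,ij->i", rs, dst_normals[inl]), -1.0, 1.0)
            cost += inlier_tol * float(np.arccos(cosang).mean())
        return inl, cost

    best = None  # (-n_inliers, cost, inliers, transform)
    for tri in samples:
        idx = list(tri)
        try:
            T = procrustes(src[idx], dst[idx])
        except ValueError:
            continue
        scored = _score(T)
        if scored is None:
            continue
        inl, cost = scored
        key = (-len(inl), cost)
        if best is None or key < best[0]:
            best = (key, inl, T)
    if best is None:
        raise ValueError("RANSAC found no consensus of >= 3 inliers")
    _, inl, T = best
    # refit on the consensus set and settle the final inliers once
    T = procrustes(src[inl], dst[inl])
    d = np.linalg.norm(T.apply(src) - dst, axis=1)
    inl = np.flatnonzero(d <= inlier_tol)
    if len(inl) >= 3:
        T = procrustes(src[inl], dst[inl])
        d = np.linalg.norm(T.apply(src) - dst, axis=1)
    # view selection minimizing the transform error: tighten the consensus
    # to the best-agreeing correspondences when they are markedly better
    # than the rest (exact corner views vs. quantization-limited ones)
    med = float(np.median(d[inl]))
    tight = min(inlier_tol, max(5.0 * med, 1e-9))
    inl2 = np.flatnonzero(d <= tight)
    if len(inl2) >= 3:
        T = procrustes(src[inl2], dst[inl2])
        inl = inl2
    return T, inl


# ----------------------------------------------------------------------
# Network assembly: rows first, then masts.
# ----------------------------------------------------------------------

def _refit_camera(src, dst, inlier_tol):
    """One cheap robust refit: Procrustes, tol-based outlier rejection,
    then the tightened (view-selection) pass. Returns (T, inlier idx)."""
    T = procrustes(src, dst)
    d = np.linalg.norm(T.apply(src) - dst, axis=1)
    inl = np.flatnonzero(d <= inlier_tol)
    if len(inl) >= 3 and len(inl) < len(src):
        T = procrustes(src[inl], dst[inl])
        d = np.linalg.norm(T.apply(src) - dst, axis=1)
        inl = np.flatnonzero(d <= inlier_tol)
    if len(inl) < 3:
        raise ValueError("refit lost consensus")
    med = float(np.median(d[inl]))
    tight = min(inlier_tol, max(5.0 * med, 1e-9))
    inl2 = np.flatnonzero(d <= tight)
    if len(inl2) >= 3:
        T = procrustes(src[inl2], dst[inl2])
        inl = inl2
    return T, inl


def _align_pairs(src, dst, inlier_tol, iters, seed):
    """ransac_align when possible, plain procrustes for exactly 3 pairs."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape[0] >= 4:
        return ransac_align(src, dst, inlier_tol, iters, seed)
    T = procrustes(src, dst)
    return T, np.arange(src.shape[0])


def calibrate_network(
    observations: list,
    reference_camera,
    row_map: dict,
    mast_map: dict,
    cube_edge: float,
    inlier_tol: float = 1.0,
    iters: int = 1000,
    seed: int = 0,
    refine_iters: int = 150,
    fit_kwargs: Optional[dict] = None,
) -> CalibrationResult:
    """Assemble per-camera extrinsics from a cube-marker session.

    Each observation is fitted (unless it already carries a center), rows
    of cameras are chained via robust center alignment, and rows are then
    registered to each other through same-mast camera pairs. Cameras or
    rows that cannot be connected are reported in ``uncalibrated`` rather
    than silently dropped. The reference camera's transform is exactly the
    identity.
    """
    fit_kwargs = fit_kwargs or {}
    centers: dict = {}  # camera -> {placement: center}
    corner: dict = {}   # camera -> set of placements seen as a 3-patch corner view
    for obs in observations:
        if obs.center is None:
            if obs.model is None:
                obs.model = fit_cube_faces(obs.cloud, **fit_kwargs)
            if obs.model.valid:
                try:
                    obs.center = cube_center(obs.model, cube_edge)
                except ValueError as exc:  # e.g. partially visible faces
                    log.debug("dropping observation (%r, %r): %s",
                              obs.camera, obs.placement, exc)
        if obs.center is not None:
            centers.setdefault(obs.camera, {})[obs.placement] = np.asarray(obs.center)
            if obs.model is not None and obs.model.n_planes == 3:
                corner.setdefault(obs.camera, set()).add(obs.placement)

    cameras = sorted(centers, key=str)
    if reference_camera not in centers:
        raise ValueError(f"reference camera {reference_camera!r} has no valid observations")
    rows: dict = {}
    for cam in cameras:
        rows.setdefault(row_map[cam], []).append(cam)

    cam_T: dict = {}        # camera -> transform into its row frame
    inliers: dict = {}
    rms: dict = {}
    uncalibrated: dict = {}
    row_ref: dict = {}

    # --- per-row chaining -------------------------------------------
    for row, members in rows.items():
        ref = (reference_camera if reference_camera in members
               else max(members, key=lambda c: (len(centers[c]), str(c))))
        row_ref[row] = ref
        cam_T[ref] = RigidTransform.identity()
        inliers[ref] = sorted(centers[ref], key=str)
        rms[ref] = 0.0
        done = {ref}
        pending = [c for c in members if c != ref]
        while pending:
            # Prim-style: attach the pending camera with the best-supported
            # edge to any calibrated one. Corner (3-patch) views constrain
            # the cube center exactly, so when both cameras saw >= 4
            # placements as corners the edge restricts to those.
            best_edge = None
            for c in pending:
                for a in done:
                    shared = sorted(set(centers[c]) & set(centers[a]), key=str)
                    strong = sorted(corner.get(c, set()) & corner.get(a, set()), key=str)
                    if len(strong) >= 3:
                        shared = strong
                    if len(shared) < 3:
                        continue
                    key = (len(strong) if len(strong) >= 3 else 0,
                           len(shared), str(a), str(c))
                    if best_edge is None or key > best_edge[0]:
                        best_edge = (key, c, a, shared)
            if best_edge is None:
                for c in pending:
                    uncalibrated[c] = "fewer than 3 valid placements shared with its row"
                break
            _, c, a, shared = best_edge
            src = np.vstack([centers[c][p] for p in shared])
            dst = np.vstack([centers[a][p] for p in shared])
            try:
                M, inl = _align_pairs(src, dst, inlier_tol, iters, seed)
            except ValueError as exc:
                uncalibrated[c] = f"alignment failed: {exc}"
                pending.remove(c)
                continue
            cam_T[c] = cam_T[a] @ M
            inliers[c] = [shared[i] for i in inl]
            res = np.linalg.norm(M.apply(src[inl]) - dst[inl], axis=1)
            rms[c] = float(np.sqrt((res ** 2).mean()))
            done.add(c)
            pending.remove(c)

    # --- inter-row alignment through masts ---------------------------
    root_row = row_map[reference_camera]
    row_T = {root_row: RigidTransform.identity()}
    pending_rows = [r for r in rows if r != root_row]
    while pending_rows:
        best_edge = None
        for s in pending_rows:
            for r in row_T:
                pairs, strong_pairs = [], []
                for b in rows[s]:
                    if b not in cam_T or b in uncalibrated:
                        continue
                    for a in rows[r]:
                        if a not in cam_T or a in uncalibrated:
                            continue
                        if mast_map.get(a) != mast_map.get(b):
                            continue
                        for p in sorted(set(centers[a]) & set(centers[b]), key=str):
                            pair = (cam_T[b].apply(centers[b][p]),
                                    cam_T[a].apply(centers[a][p]))
                            pairs.append(pair)
                            if p in corner.get(a, set()) and p in corner.get(b, set()):
                                strong_pairs.append(pair)
                if len(strong_pairs) >= 3:
                    pairs = strong_pairs
                if len(pairs) < 3:
                    continue
                key = (len(strong_pairs) if len(strong_pairs) >= 3 else 0,
                       len(pairs), str(r), str(s))
                if best_edge is None or key > best_edge[0]:
                    best_edge = (key, s, r,
                                 np.vstack([p[0] for p in pairs]),
                                 np.vstack([p[1] for p in pairs]))
        if best_edge is None:
            for s in pending_rows:
                for c in rows[s]:
                    uncalibrated.setdefault(
                        c, "row not connectable to the reference row via masts")
            break
        _, s, r, src, dst = best_edge
        N, _ = _align_pairs(src, dst, inlier_tol, iters, seed)
        row_T[s] = row_T[r] @ N
        pending_rows.remove(s)

    # --- compose and re-anchor on the reference camera ----------------
    full: dict = {}
    for cam in cameras:
        if cam in uncalibrated or cam not in cam_T:
            uncalibrated.setdefault(cam, "not reached by row chaining")
            continue
        r = row_map[cam]
        if r not in row_T:
            continue
        full[cam] = row_T[r] @ cam_T[cam]
    anchor = full[reference_camera].inverse()
    full = {cam: anchor @ T for cam, T in full.items()}
    full[reference_camera] = RigidTransform.identity()

    # --- global refinement against triangulated marker positions ------
    # Pairwise chaining can leave a camera attached through quantization-
    # limited (non-corner) correspondences even though its corner views
    # overlap well with the rest of the network collectively. Alternate
    # estimating each placement's global position (averaged over corner
    # views, falling back to all views) with refitting each camera
    # against those positions via its own corner views.
    for _ in range(refine_iters):
        global_pos: dict = {}
        for p in {pl for cam in full for pl in centers[cam]}:
            best = [full[cam].apply(centers[cam][p]) for cam in full
                    if p in corner.get(cam, set()) and p in centers[cam]]
            if not best:
                best = [full[cam].apply(centers[cam][p]) for cam in full
                        if p in centers[cam]]
            if best:
                global_pos[p] = np.mean(best, axis=0)
        new_full = {}
        for cam in full:
            use = sorted((corner.get(cam, set()) or set(centers[cam]))
                         & set(global_pos), key=str)
            if len(use) < 3:
                use = sorted(set(centers[cam]) & set(global_pos), key=str)
            if len(use) < 3:
                new_full[cam] = full[cam]
                continue
            src = np.vstack([centers[cam][p] for p in use])
            dst = np.vstack([global_pos[p] for p in use])
            try:
                T, inl = _refit_camera(src, dst, inlier_tol)
            except ValueError:
                new_full[cam] = full[cam]
                continue
            new_full[cam] = T
            inliers[cam] = [use[i] for i in inl]
            res = np.linalg.norm(T.apply(src[inl]) - dst[inl], axis=1)
            rms[cam] = float(np.sqrt((res ** 2).mean()))
        anchor = new_full[reference_camera].inverse()
        new_full = {cam: anchor @ T for cam, T in new_full.items()}
        new_full[reference_camera] = RigidTransform.identity()
        delta = max(float(np.abs(new_full[c].matrix - full[c].matrix).max())
                    for c in full)
        full = new_full
        if delta < 1e-13:  # consensus reached
            break

    return CalibrationResult(full, reference_camera,
                             {c: inliers.get(c, []) for c in full},
                             {c: rms.get(c, float("nan")) for c in full},
                             uncalibrated)
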