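import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from anthromesh.calibration import (
    MarkerObservation,
    calibrate_network,
    cube_center,
    fit_cube_faces,
    procrustes,
    ransac_align,
)
from anthromesh.cloud import PointCloud
from anthromesh.transforms import RigidTransform

from conftest import random_rigid_transform


def three_face_cloud(edge=30.0, n_per_face=400, noise=0.0, seed=0,
                     transform=None, view_dir=(0.0, 0.0, 1.0)):
    """Points on the three faces of a cube corner, optional range noise.

    The cube is centered at the origin of the marker frame with the
    (+x, +y, +z) corner toward the camera at -view_dir * inf; noise is
    applied along the viewing direction, as a depth sensor would.
    """
    rng = np.random.default_rng(seed)
    half = edge / 2
    pts = []
    for ax in range(3):
        uv = rng.uniform(-half, half, size=(n_per_face, 2))
        face = np.zeros((n_per_face, 3))
        face[:, ax] = half
        face[:, (ax + 1) % 3] = uv[:, 0]
        face[:, (ax + 2) % 3] = uv[:, 1]
        pts.append(face)
    pts = np.vstack(pts)
    if noise:
        v = np.asarray(view_dir) / np.linalg.norm(view_dir)
        pts = pts + rng.normal(0, noise, size=len(pts))[:, None] * v
    if transform is not None:
        pts = transform.apply(pts)
    return PointCloud(pts)


CAMERA = (60.0, 60.0, 60.0)  # looks at the (+,+,+) corner from outside


# ------------------------------------------------------ cube fitting

def test_noiseless_three_face_fit_is_exact():
    cloud = three_face_cloud()
    model = fit_cube_faces(cloud, camera_origin=CAMERA)
    assert model.valid and model.n_planes == 3
    assert model.residual < 1e-9
    normals = np.vstack([p.normal for p in model.planes])
    gram = normals @ normals.T
    assert np.allclose(gram, np.eye(3), atol=1e-9)  # exactly orthogonal


def test_noisy_fit_recovers_normals_within_one_degree():
    sigma = 0.2
    cloud = three_face_cloud(noise=sigma, seed=11, view_dir=(1.0, 1.0, 1.0))
    model = fit_cube_faces(cloud, camera_origin=CAMERA)
    assert model.valid
    assert model.residual <= 1.1 * sigma
    truth = np.eye(3)
    for p in model.planes:
        best = max(abs(p.normal @ t) for t in truth)
        assert np.degrees(np.arccos(min(best, 1.0))) < 1.0


def test_single_face_cloud_yields_one_plane():
    rng = np.random.default_rng(0)
    uv = rng.uniform(-10, 10, size=(300, 2))
    pts = np.column_stack([uv[:, 0], uv[:, 1], np.full(300, 15.0)])
    model = fit_cube_faces(PointCloud(pts), camera_origin=(0, 0, 60))
    assert model.valid and model.n_planes == 1
    assert abs(model.planes[0].normal @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-9)


def test_degenerate_cloud_gives_invalid_model():
    model = fit_cube_faces(PointCloud(np.zeros((5, 3))))
    assert not model.valid


def test_residual_history_non_increasing():
    cloud = three_face_cloud(noise=0.3, seed=5, view_dir=(1.0, 1.0, 1.0))
    model = fit_cube_faces(cloud, camera_origin=CAMERA)
    hist = model.residual_history
    assert len(hist) >= 1
    assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))


# ------------------------------------------------------- cube centers

def test_three_plane_center_exact_and_equivariant(rng):
    cloud = three_face_cloud()
    model = fit_cube_faces(cloud, camera_origin=CAMERA)
    assert np.allclose(cube_center(model, 30.0), 0.0, atol=1e-9)

    T = random_rigid_transform(rng, t_scale=10.0)
    moved = three_face_cloud(transform=T)
    cam2 = T.apply(np.asarray(CAMERA))
    model2 = fit_cube_faces(moved, camera_origin=cam2)
    assert np.allclose(cube_center(model2, 30.0), T.translation, atol=1e-8)


def test_noisy_center_median_error_below_two_millimeters():
    errs = []
    for seed in range(100):
        cloud = three_face_cloud(n_per_face=300, noise=0.2, seed=seed,
                                 view_dir=(1.0, 1.0, 1.0))
        model = fit_cube_faces(cloud, camera_origin=CAMERA)
        if not model.valid:
            continue
        errs.append(np.linalg.norm(cube_center(model, 30.0)))
    assert len(errs) >= 90
    assert np.median(errs) < 0.2


def test_center_of_invalid_model_raises():
    model = fit_cube_faces(PointCloud(np.zeros((5, 3))))
    with pytest.raises(ValueError):
        cube_center(model, 30.0)


# --------------------------------------------------------- procrustes

def test_procrustes_identity_and_exact_recovery(rng):
    src = rng.normal(size=(10, 3)) * 20
    assert np.allclose(procrustes(src, src).matrix, np.eye(4), atol=1e-9)
    T = random_rigid_transform(rng)
    got = procrustes(src, T.apply(src))
    assert np.allclose(got.matrix, T.matrix, atol=1e-9)


def test_procrustes_rejects_collinear_points():
    src = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="collinear"):
        procrustes(src, src + 1.0)


def test_procrustes_matches_numeric_optimizer(rng):
    """The closed-form solution attains the same least-squares cost as a
    direct numeric minimization over a rotation-vector parameterization."""
    src = rng.normal(size=(12, 3)) * 15
    T = random_rigid_transform(rng)
    dst = T.apply(src) + rng.normal(0, 0.5, size=src.shape)
    got = procrustes(src, dst)
    cost_closed = np.sum((got.apply(src) - dst) ** 2)

    def cost(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        return np.sum((src @ R.T + x[3:] - dst) ** 2)

    res = minimize(cost, np.zeros(6), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    assert cost_closed <= res.fun + 1e-6


# ------------------------------------------------------------- RANSAC

def test_ransac_exact_pairs_all_inliers(rng):
    src = rng.normal(size=(6, 3)) * 20
    T = random_rigid_transform(rng)
    got, inliers = ransac_align(src, T.apply(src), inlier_tol=1.0, seed=0)
    assert np.allclose(got.matrix, T.matrix, atol=1e-9)
    assert list(inliers) == list(range(6))


def test_ransac_excludes_gross_outlier_exactly(rng):
    src = rng.normal(size=(6, 3)) * 20
    T = random_rigid_transform(rng)
    dst = T.apply(src)
    dst[2] += np.array([20.0, 0.0, 0.0])  # one corrupted correspondence
    got, inliers = ransac_align(src, dst, inlier_tol=1.0, seed=0)
    assert sorted(inliers) == [0, 1, 3, 4, 5]
    assert np.allclose(got.matrix, T.matrix, atol=1e-6)


def test_ransac_matches_exhaustive_subset_oracle(rng):
    """The consensus set equals the best found by enumerating all 3-subsets."""
    n = 8
    src = rng.normal(size=(n, 3)) * 20
    T = random_rigid_transform(rng)
    dst = T.apply(src) + rng.normal(0, 0.1, size=(n, 3))
    dst[5] += 15.0
    tol = 1.0
    _, inliers = ransac_align(src, dst, inlier_tol=tol, seed=1)

    from itertools import combinations

    best = set()
    for tri in combinations(range(n), 3):
        try:
            M = procrustes(src[list(tri)], dst[list(tri)])
        except ValueError:
            continue
        d = np.linalg.norm(M.apply(src) - dst, axis=1)
        inl = set(np.flatnonzero(d <= tol))
        if len(inl) > len(best):
            best = inl
    assert set(inliers) == best


def test_ransac_scores_normal_agreement(rng):
    """With patch normals supplied, a model aligning the normals wins over
    one that only matches the centers."""
    src = rng.normal(size=(6, 3)) * 10
    T = random_rigid_transform(rng)
    dst = T.apply(src)
    nrm = rng.normal(size=(6, 3))
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    got, inliers = ransac_align(src, dst, inlier_tol=1.0, seed=0,
                                src_normals=nrm, dst_normals=T.apply_vectors(nrm))
    assert np.allclose(got.matrix, T.matrix, atol=1e-9)
    assert len(inliers) == 6


def test_ransac_no_consensus_raises(rng):
    src = rng.normal(size=(6, 3)) * 20
    dst = rng.normal(size=(6, 3)) * 20  # unrelated: no rigid consensus
    with pytest.raises(ValueError, match="consensus"):
        ransac_align(src, dst, inlier_tol=1e-6, seed=0)


# ----------------------------------------------------- network assembly

def _center_observations(cameras, placements, noise=0.0, seed=0):
    """Observations carrying exact (optionally jittered) cube centers."""
    rng = np.random.default_rng(seed)
    obs = []
    for ci, pose in enumerate(cameras):
        inv = pose.inverse()
        for pi, c_world in enumerate(placements):
            c = inv.apply(c_world)
            if noise:
                c = c + rng.normal(0, noise, size=3)
            obs.append(MarkerObservation(ci, pi, center=c))
    return obs


def test_two_camera_network_recovers_exact_pose(rng):
    cams = [random_rigid_transform(rng, 100.0) for _ in range(2)]
    placements = [rng.uniform(-20, 20, size=3) for _ in range(6)]
    obs = _center_observations(cams, placements)
    res = calibrate_network(obs, 0, {0: 0, 1: 0}, {0: 0, 1: 1}, cube_edge=30.0)
    truth = cams[0].inverse() @ cams[1]
    assert np.allclose(res.transforms[1].matrix, truth.matrix, atol=1e-9)
    assert np.allclose(res.transforms[0].matrix, np.eye(4))


def test_disconnected_camera_is_reported(rng):
    cams = [random_rigid_transform(rng, 100.0) for _ in range(3)]
    placements = [rng.uniform(-20, 20, size=3) for _ in range(6)]
    obs = _center_observations(cams[:2], placements)
    # camera 2 contributes a single valid placement: cannot be chained
    obs.append(MarkerObservation(2, 0, center=cams[2].inverse().apply(placements[0])))
    res = calibrate_network(obs, 0, {0: 0, 1: 0, 2: 0}, {0: 0, 1: 1, 2: 2}, 30.0)
    assert 2 in res.uncalibrated
    assert 2 not in res.transforms


def test_two_row_network_chains_through_masts(rng):
    cams = [random_rigid_transform(rng, 100.0) for _ in range(4)]
    placements = [rng.uniform(-20, 20, size=3) for _ in range(8)]
    obs = _center_observations(cams, placements)
    row_map = {0: 0, 1: 0, 2: 1, 3: 1}
    mast_map = {0: 0, 1: 1, 2: 0, 3: 1}
    res = calibrate_network(obs, 0, row_map, mast_map, 30.0)
    for c in range(4):
        truth = cams[0].inverse() @ cams[c]
        assert np.allclose(res.transforms[c].matrix, truth.matrix, atol=1e-8)


def test_pose_error_decreases_with_more_placements(rng):
    """Median pose error over trials shrinks from 4 to 12 placements."""
    sigma = 0.3
    errs = {4: [], 12: []}
    for n_pl in errs:
        for trial in range(20):
            trial_rng = np.random.default_rng(1000 + trial)
            cams = [random_rigid_transform(trial_rng, 100.0) for _ in range(3)]
            placements = [trial_rng.uniform(-25, 25, size=3) for _ in range(n_pl)]
            obs = _center_observations(cams, placements, noise=sigma, seed=trial)
            res = calibrate_network(obs, 0, {c: 0 for c in range(3)},
                                    {c: c for c in range(3)}, 30.0,
                                    inlier_tol=3.0)
            for c in (1, 2):
                _, tr = (cams[0].inverse() @ cams[c]).distance_to(res.transforms[c])
                errs[n_pl].append(tr)
    assert np.median(errs[12]) < np.median(errs[4])
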