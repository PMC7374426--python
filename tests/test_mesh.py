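import numpy as np
import pytest
import trimesh

from anthromesh.mesh import (
    Plane,
    Ray,
    TriangleMesh,
    exact_mesh_volume,
    exact_plane_section,
    load_mesh,
    loop_length,
    ray_fan_first_hits,
    ray_first_hit,
    save_mesh,
)
from anthromesh.shapes import make_cube

from conftest import random_convex_prism, random_rigid_transform


def centered_cube(side=15.0):
    mesh = make_cube(side)
    mesh.vertices[:, 1] -= side / 2
    return mesh


# ---------------------------------------------------------------- I/O

@pytest.mark.parametrize("ext", ["ply", "obj"])
def test_mesh_roundtrip(tmp_path, ext):
    mesh = make_cube(15.0)
    path = tmp_path / f"cube.{ext}"
    save_mesh(mesh, str(path))
    back = load_mesh(str(path))
    assert back.n_vertices == 8 and back.n_faces == 12
    # same vertex set (order may differ per writer)
    a = np.array(sorted(map(tuple, np.round(mesh.vertices, 6))))
    b = np.array(sorted(map(tuple, np.round(back.vertices, 6))))
    assert np.allclose(a, b, atol=1e-6)


def test_degenerate_faces_dropped(caplog):
    v = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]
    f = [[0, 1, 2], [1, 1, 2], [1, 3, 2]]  # middle face has zero area
    with caplog.at_level("WARNING"):
        mesh = TriangleMesh(v, f)
    assert mesh.n_faces == 2
    assert any("degenerate" in r.message for r in caplog.records)


def test_load_invalid_file_raises(tmp_path):
    bad = tmp_path / "broken.ply"
    bad.write_text("ply\nformat ascii 1.0\nelement vertex nonsense\n")
    with pytest.raises((ValueError, FileNotFoundError)):
        load_mesh(str(bad))
    with pytest.raises(FileNotFoundError):
        load_mesh(str(tmp_path / "missing.ply"))


# ------------------------------------------------------- ray casting

def test_ray_hits_axis_aligned_face():
    mesh = centered_cube(15.0)
    hit = ray_first_hit(mesh, Ray([20, 0, 0], [-1, 0, 0]))
    assert hit is not None
    point, _, dist = hit
    assert np.allclose(point, [7.5, 0, 0], atol=1e-9)
    assert dist == pytest.approx(12.5, abs=1e-9)


def test_ray_away_from_cube_misses():
    mesh = centered_cube(15.0)
    assert ray_first_hit(mesh, Ray([20, 0, 0], [1, 0, 0])) is None


def _brute_force_first_hit(mesh, origin, direction):
    """Independent per-triangle Moller-Trumbore, plain loops."""
    best = None
    for tri in mesh.triangles:
        v0, v1, v2 = tri
        e1, e2 = v1 - v0, v2 - v0
        p = np.cross(direction, e2)
        det = e1 @ p
        if abs(det) < 1e-14:
            continue
        t0 = origin - v0
        u = (t0 @ p) / det
        q = np.cross(t0, e1)
        v = (direction @ q) / det
        t = (e2 @ q) / det
        if u < -1e-9 or v < -1e-9 or u + v > 1 + 1e-9 or t < -1e-9:
            continue
        if best is None or t < best:
            best = t
    return best


def test_first_hit_matches_exhaustive_triangle_oracle(rng):
    """First-hit distances agree with the brute-force all-triangle minimum
    on random convex meshes."""
    checked = 0
    for _ in range(8):
        pts = rng.normal(size=(30, 3)) * 10
        hull = trimesh.convex.convex_hull(pts)
        mesh = TriangleMesh(np.asarray(hull.vertices), np.asarray(hull.faces))
        origins = rng.normal(size=(40, 3)) * 40
        targets = rng.normal(size=(40, 3)) * 5
        dirs = targets - origins
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        hitmask, _, _, dist = ray_fan_first_hits(mesh, origins, dirs)
        for o, d, h, t in zip(origins, dirs, hitmask, dist):
            expected = _brute_force_first_hit(mesh, o, d)
            if expected is None:
                assert not h
            else:
                assert h and t == pytest.approx(expected, abs=1e-9)
            checked += 1
    assert checked >= 300


# ----------------------------------------------------- exact sections

def test_cube_mid_height_section_is_a_square_loop(cube15):
    loops = exact_plane_section(cube15, Plane(np.array([0.0, 1.0, 0.0]), 7.5))
    assert len(loops) == 1
    assert loop_length(loops[0]) == pytest.approx(60.0, abs=1e-9)


def test_tangent_plane_yields_no_loop(cube15):
    # plane exactly through the top face touches a measure-zero set
    loops = exact_plane_section(cube15, Plane(np.array([0.0, 1.0, 0.0]), 15.0 + 1e-9))
    assert loops == []


def test_section_length_matches_face_clipping_oracle(rng):
    """Loop length equals the summed lengths of per-triangle plane clips."""
    for _ in range(10):
        mesh, _, height = random_convex_prism(rng)
        y = rng.uniform(0.2, 0.8) * height
        plane = Plane(np.array([0.0, 1.0, 0.0]), y)
        loops = exact_plane_section(mesh, plane)
        total = sum(loop_length(lp) for lp in loops)
        # oracle: clip every triangle against the plane independently
        acc = 0.0
        for tri in mesh.triangles:
            d = tri[:, 1] - y
            pts = []
            for i in range(3):
                j = (i + 1) % 3
                if d[i] == 0.0:
                    pts.append(tri[i])
                if d[i] * d[j] < 0:
                    s = d[i] / (d[i] - d[j])
                    pts.append(tri[i] + s * (tri[j] - tri[i]))
            if len(pts) >= 2:
                acc += float(np.linalg.norm(pts[1] - pts[0]))
        assert total == pytest.approx(acc, rel=1e-9)


def test_section_loop_is_ccw_about_normal(cube15):
    loops = exact_plane_section(cube15, Plane(np.array([0.0, 1.0, 0.0]), 7.5))
    lp = loops[0]
    center = lp.mean(axis=0)
    cr = np.cross(lp - center, np.roll(lp, -1, axis=0) - center).sum(axis=0)
    assert cr @ np.array([0.0, 1.0, 0.0]) > 0


# ------------------------------------------------------------ volume

def test_cube_volumes(cube15, cube50):
    assert exact_mesh_volume(cube15) == pytest.approx(3375.0, abs=1e-9)
    assert exact_mesh_volume(cube50) == pytest.approx(125000.0, abs=1e-6)


def test_volume_rigid_invariance_and_reordering(cube15, rng):
    T = random_rigid_transform(rng)
    moved = cube15.transformed(T)
    assert exact_mesh_volume(moved) == pytest.approx(3375.0, rel=1e-9)
    perm = rng.permutation(cube15.n_faces)
    reordered = TriangleMesh(cube15.vertices, cube15.faces[perm])
    assert exact_mesh_volume(reordered) == pytest.approx(3375.0, rel=1e-12)


def test_open_mesh_volume_raises_with_edge_count(cube15):
    open_mesh = TriangleMesh(cube15.vertices, cube15.faces[:-1])
    with pytest.raises(ValueError, match="3 open edges"):
        exact_mesh_volume(open_mesh)


def test_section_length_invariant_under_in_plane_rotation(cube15):
    from anthromesh.transforms import RigidTransform

    base = loop_length(exact_plane_section(cube15, Plane(np.array([0.0, 1.0, 0.0]), 7.5))[0])
    rot = RigidTransform.from_axis_angle([0, 1, 0], 0.37)
    rotated = cube15.transformed(rot)
    got = loop_length(exact_plane_section(rotated, Plane(np.array([0.0, 1.0, 0.0]), 7.5))[0])
    assert got == pytest.approx(base, rel=1e-9)
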