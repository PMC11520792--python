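"""Rigid registration: closed-form fit, initialization, ICP, merging."""

import numpy as np
import pytest

from replica_accuracy import (
    ICPConfig,
    RegistrationError,
    RigidTransform,
    SurfaceMesh,
    best_rigid,
    icp_register,
    initial_align,
    merge_half_scans,
)

from conftest import icosphere
from oracles import best_proper_rotation_residual


def random_transform(seed, max_angle=20.0, max_shift=5.0):
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    return RigidTransform.from_axis_angle(
        axis, rng.uniform(-max_angle, max_angle), rng.uniform(-max_shift, max_shift, 3)
    )


# ---------------------------------------------------------------------------
# RigidTransform
# ---------------------------------------------------------------------------


def test_transform_group_operations():
    t1 = random_transform(1)
    t2 = random_transform(2)
    pts = np.random.default_rng(0).normal(size=(20, 3))
    assert np.allclose(t1.compose(t2).apply(pts), t1.apply(t2.apply(pts)))
    assert np.allclose(t1.compose(t1.inverse()).apply(pts), pts, atol=1e-12)
    rt = RigidTransform.from_matrix(t1.to_matrix())
    assert np.allclose(rt.rotation, t1.rotation)
    # invariants hold under long composition chains
    acc = RigidTransform.identity()
    for k in range(200):
        acc = acc.compose(t1)
    r = acc.rotation
    assert np.allclose(r @ r.T, np.eye(3), atol=1e-9)


def test_transform_rejects_improper_rotation():
    with pytest.raises(ValueError):
        RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
    with pytest.raises(ValueError):
        RigidTransform(np.eye(3) * 1.01, np.zeros(3))


# ---------------------------------------------------------------------------
# best_rigid
# ---------------------------------------------------------------------------


def test_best_rigid_identity_and_exact_recovery():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(30, 3))
    t = best_rigid(pts, pts)
    assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
    assert np.allclose(t.translation, 0, atol=1e-12)

    gt = RigidTransform.from_axis_angle([0, 0, 1], 30.0, (1.0, -2.0, 0.5))
    rec = best_rigid(pts, gt.apply(pts))
    assert np.allclose(rec.to_matrix(), gt.to_matrix(), atol=1e-9)
    resid = np.linalg.norm(rec.apply(pts) - gt.apply(pts), axis=1)
    assert resid.max() < 1e-9


def test_best_rigid_reflected_target_stays_proper():
    # a mirrored correspondence has no exact proper-rotation solution; the
    # result must still be a rotation and must attain the brute-force
    # minimum residual over SO(3)
    src = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.3, 1.0]])
    tgt = src * np.array([1.0, 1.0, -1.0])  # reflection
    rec = best_rigid(src, tgt)
    assert np.linalg.det(rec.rotation) == pytest.approx(1.0, abs=1e-9)
    rms = np.sqrt(np.mean(np.linalg.norm(rec.apply(src) - tgt, axis=1) ** 2))
    oracle = best_proper_rotation_residual(src, tgt)
    assert rms == pytest.approx(oracle, abs=1e-6)


def test_best_rigid_conjugation_invariance():
    rng = np.random.default_rng(5)
    src = rng.normal(size=(25, 3))
    tgt = rng.normal(size=(25, 3))
    base = best_rigid(src, tgt)
    g = random_transform(7)
    moved = best_rigid(g.apply(src), g.apply(tgt))
    # transforming both sets by g conjugates the solution: moved = g base g^-1
    expect = g.compose(base).compose(g.inverse())
    assert np.allclose(moved.to_matrix(), expect.to_matrix(), atol=1e-9)


def test_best_rigid_degenerate_inputs():
    with pytest.raises(RegistrationError):
        best_rigid(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.outer(np.arange(5.0), [1.0, 0, 0])
    with pytest.raises(RegistrationError):
        best_rigid(line, line + 1.0)


# ---------------------------------------------------------------------------
# initial alignment
# ---------------------------------------------------------------------------


def test_initial_align_never_worse_than_identity(premolar):
    _, mesh = premolar
    t = initial_align(mesh, mesh)
    d = mesh.query().distances(t.apply(mesh.vertices[::20]))
    assert np.sqrt((d**2).mean()) < 1e-9


def test_initial_align_captures_large_rotation(premolar):
    _, mesh = premolar
    gt = RigidTransform.from_axis_angle([0, 0, 1], 170.0, (2.0, 1.0, -3.0))
    src = gt.apply_mesh(mesh)
    t = initial_align(src, mesh)
    d = mesh.query().distances(t.apply(src.vertices[::20]))
    assert np.sqrt((d**2).mean()) < 1.0  # coarse capture


def test_initial_align_sphere_falls_back_to_centroid():
    s = icosphere(3.0, 3)
    moved = SurfaceMesh(s.vertices + np.array([3.0, 0.0, 0.0]), s.faces)
    t = initial_align(moved, s)
    assert np.allclose(t.translation, [-3.0, 0.0, 0.0], atol=0.05)


# ---------------------------------------------------------------------------
# ICP
# ---------------------------------------------------------------------------


def test_icp_identity_on_same_mesh(premolar):
    _, mesh = premolar
    res = icp_register(mesh, mesh, ICPConfig(subsample_count=1000))
    # matrix-level identity (the angle extracted via arccos has a noise
    # floor of ~1e-6 deg even for an exactly-identity rotation)
    assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-9)
    assert np.linalg.norm(res.transform.translation) < 1e-9
    assert res.rms_history[-1] < 1e-9


@pytest.mark.parametrize("kind", ["premolar", "molar"])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_icp_recovers_random_transform(kind, seed, phantoms):
    _, mesh = phantoms[kind]
    gt = random_transform(seed * 13 + 1)
    src = gt.apply_mesh(mesh)
    res = icp_register(src, mesh, ICPConfig(subsample_count=1500, seed=seed))
    err = res.transform.compose(gt)
    assert err.rotation_angle_deg() < 0.1
    assert np.linalg.norm(err.translation) < 0.02
    assert np.all(np.diff(res.rms_history) <= 1e-9)


def test_icp_residual_bounded_by_noise(premolar):
    from replica_accuracy import simulate_replica

    _, mesh = premolar
    sd = 0.05
    noisy = simulate_replica(mesh, sd, seed=2, smooth_iterations=0)
    src = random_transform(3, max_angle=10, max_shift=2).apply_mesh(noisy)
    res = icp_register(src, mesh, ICPConfig(subsample_count=1500, seed=0))
    assert res.final_rms < 3 * sd


# ---------------------------------------------------------------------------
# half-scan merging
# ---------------------------------------------------------------------------


def split_mesh(mesh, z, overlap):
    f = mesh.faces
    zf = mesh.vertices[f][:, :, 2]
    top = SurfaceMesh(mesh.vertices.copy(), f[(zf > z - overlap).all(axis=1)])
    bottom = SurfaceMesh(mesh.vertices.copy(), f[(zf < z + overlap).all(axis=1)])
    return top, bottom


def test_merge_identical_halves_welds_to_input(premolar):
    _, mesh = premolar
    merged = merge_half_scans(mesh, mesh)
    assert merged.n_vertices == mesh.n_vertices


def test_merge_displaced_halves_recovers_surface(premolar):
    _, mesh = premolar
    zmid = mesh.vertices[:, 2].mean()
    top, bottom = split_mesh(mesh, zmid, 1.0)  # 2 mm overlap band
    pre = RigidTransform.from_axis_angle([1, 0, 0], 2.0, (0.3, 0.2, -0.1))
    merged = merge_half_scans(
        top, pre.apply_mesh(bottom), ICPConfig(subsample_count=1200)
    )
    d = mesh.query().distances(merged.vertices)
    assert d.max() < 0.05


def test_merge_disjoint_halves_is_rejected(premolar):
    _, mesh = premolar
    zmid = mesh.vertices[:, 2].mean()
    f = mesh.faces
    zf = mesh.vertices[f][:, :, 2]
    top = SurfaceMesh(mesh.vertices.copy(), f[(zf > zmid + 2).all(axis=1)])
    bottom = SurfaceMesh(mesh.vertices.copy(), f[(zf < zmid - 2).all(axis=1)])
    with pytest.raises(RegistrationError):
        merge_half_scans(top, bottom, ICPConfig(subsample_count=1200))
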