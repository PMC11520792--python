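"""Phantom generator: determinism, topology, voxelization, deformations."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from replica_accuracy import (
    SurfaceMesh,
    TOOTH_KINDS,
    canal_segments,
    deform_bump,
    deformity_site,
    make_phantom,
    simulate_replica,
    voxelize,
)
from replica_accuracy.geometry import GeometryError

from conftest import COARSE_PITCH, icosphere
from oracles import brute_contains, slice_loop_count


@pytest.mark.parametrize("kind", TOOTH_KINDS)
def test_phantom_is_closed_genus_zero_and_deterministic(kind, phantoms):
    spec, mesh = phantoms[kind]
    assert mesh.is_closed()
    assert mesh.euler_characteristic() == 2
    assert mesh.volume > 0  # outward orientation
    spec2, mesh2 = make_phantom(kind, seed=1, pitch=COARSE_PITCH)
    assert spec == spec2
    assert np.array_equal(mesh.vertices, mesh2.vertices)
    assert np.array_equal(mesh.faces, mesh2.faces)


def test_root_count_matches_kind(phantoms):
    assert len(phantoms["premolar"][0].root_specs) == 1
    assert len(phantoms["canine"][0].root_specs) == 1
    assert len(phantoms["molar"][0].root_specs) >= 2


def test_molar_furcation_cross_section_has_two_loops(molar, premolar):
    spec, mesh = molar
    # below the furcation saddle the section separates into root lobes
    z_fur = deformity_site(spec, mesh, "furcation")[2]
    assert slice_loop_count(mesh, z_fur - 2.0) >= 2
    # a single-rooted tooth stays a single loop at root height
    pspec, pmesh = premolar
    assert slice_loop_count(pmesh, pspec.root_specs[0].base_point[2] - 4.0) == 1


def test_seed_does_not_alter_geometry():
    _, m7 = make_phantom("canine", seed=7, pitch=0.4)
    _, m8 = make_phantom("canine", seed=8, pitch=0.4)
    assert m7.n_faces == m8.n_faces
    assert np.array_equal(m7.vertices, m8.vertices)


def test_unknown_tooth_kind_raises():
    with pytest.raises(ValueError, match="tooth_kind"):
        make_phantom("incisor", seed=0)


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------


def test_voxelize_sphere_interior_count_near_analytic():
    sphere = icosphere(5.0, 5)
    vol = voxelize(sphere, spacing=0.2)
    n_inside = int((vol.values > 1600).sum())
    xs = [vol.voxel_centers_axis(k) for k in range(3)]
    grid = np.stack(np.meshgrid(*xs, indexing="ij"), axis=-1)
    analytic = int((np.linalg.norm(grid, axis=-1) < 5.0).sum())
    # agreement up to centers within the chordal sag of the faceted sphere
    assert abs(n_inside - analytic) <= 1e-3 * analytic


def test_voxelize_parity_exact_against_brute_force():
    sphere = icosphere(1.0, 1)
    vol = voxelize(sphere, spacing=0.3, pad_voxels=2)
    xs = [vol.voxel_centers_axis(k) for k in range(3)]
    grid = np.stack(np.meshgrid(*xs, indexing="ij"), axis=-1).reshape(-1, 3)
    expect = brute_contains(grid, sphere).reshape(vol.shape)
    assert ((vol.values > 1600) == expect).all()


def test_voxelize_threshold_separability_and_determinism(premolar):
    spec, mesh = premolar
    vol1 = voxelize(mesh, spacing=0.3, seed=9)
    vol2 = voxelize(mesh, spacing=0.3, seed=9)
    assert np.array_equal(vol1.values, vol2.values)
    # noise-free, blur-free: any threshold strictly between the HU levels
    # recovers exactly the same mask
    for level in (100.0, 1600.0, 1900.0):
        assert np.array_equal(vol1.values > level, vol1.values > 1000.0)


def test_voxelize_carves_canals_below_threshold(premolar):
    spec, mesh = premolar
    vol = voxelize(mesh, spacing=0.3, canal_paths=canal_segments(spec))
    assert (vol.values == 300.0).sum() > 0


def test_voxelize_rejects_open_mesh_and_bad_contrast(premolar):
    spec, mesh = premolar
    open_mesh = SurfaceMesh(mesh.vertices, mesh.faces[:-5])
    with pytest.raises(GeometryError):
        voxelize(open_mesh, spacing=0.4)
    with pytest.raises(ValueError, match="straddle"):
        voxelize(mesh, spacing=0.4, hu_hard_tissue=1500.0)


def test_voxelize_pads_background(premolar):
    _, mesh = premolar
    vol = voxelize(mesh, spacing=0.3)
    v = vol.values
    assert (v[0] == 0).all() and (v[-1] == 0).all()
    assert (v[:, 0] == 0).all() and (v[:, :, 0] == 0).all()


# ---------------------------------------------------------------------------
# deformations
# ---------------------------------------------------------------------------


def test_bump_zero_amplitude_is_identity(sphere5):
    out = deform_bump(sphere5, (0, 0, 5.0), 2.0, 0.0)
    assert np.array_equal(out.vertices, sphere5.vertices)


def test_bump_center_moves_exactly_one_amplitude():
    sphere = icosphere(5.0, 4)
    # pick an actual vertex as center so w(0)=1 applies to it exactly
    vid = int(np.argmax(sphere.vertices[:, 2]))
    center = sphere.vertices[vid]
    out = deform_bump(sphere, center, 2.0, 1.0)
    assert np.linalg.norm(out.vertices[vid] - center) == pytest.approx(1.0, abs=1e-12)
    # pole bump on a sphere: max radius grows to 5 + amplitude
    assert np.linalg.norm(out.vertices, axis=1).max() == pytest.approx(5.8 + 0.2, abs=0.25)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(
    ci=st.integers(0, 10**6),
    radius=st.floats(0.5, 3.0),
    amplitude=st.floats(-1.0, 1.0),
)
def test_bump_locality_property(ci, radius, amplitude, sphere5):
    center = sphere5.vertices[ci % sphere5.n_vertices]
    out = deform_bump(sphere5, center, radius, amplitude)
    far = np.linalg.norm(sphere5.vertices - center, axis=1) >= radius
    assert np.array_equal(out.vertices[far], sphere5.vertices[far])
    assert np.array_equal(out.faces, sphere5.faces)


# ---------------------------------------------------------------------------
# replica simulation
# ---------------------------------------------------------------------------


def test_replica_zero_noise_is_identity(sphere5):
    out = simulate_replica(sphere5, 0.0, seed=1)
    assert np.array_equal(out.vertices, sphere5.vertices)


def test_replica_noise_statistics_before_smoothing(sphere5):
    sd = 0.05
    out = simulate_replica(sphere5, sd, seed=3, smooth_iterations=0)
    disp = np.linalg.norm(out.vertices - sphere5.vertices, axis=1)
    expect = sd * np.sqrt(2 / np.pi)  # mean |N(0, sd)|
    se = sd * np.sqrt(1 - 2 / np.pi) / np.sqrt(sphere5.n_vertices)
    assert abs(disp.mean() - expect) < 3 * se


def test_replica_deterministic_per_seed(sphere5):
    a = simulate_replica(sphere5, 0.05, seed=11)
    b = simulate_replica(sphere5, 0.05, seed=11)
    assert np.array_equal(a.vertices, b.vertices)
    c = simulate_replica(sphere5, 0.05, seed=12)
    assert not np.array_equal(a.vertices, c.vertices)
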