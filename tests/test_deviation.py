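"""Deviation metrics: oracle agreement, analytic cases, sign convention."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from replica_accuracy import (
    DistanceField,
    RigidTransform,
    SurfaceMesh,
    compare_models,
    euclidean_field,
    normal_field,
    summarize,
)
from replica_accuracy.geometry import GeometryError

from conftest import icosphere
from oracles import brute_closest_distance


def test_euclidean_field_zero_on_itself(sphere5):
    f = euclidean_field(sphere5, sphere5)
    assert f.values.max() == 0.0
    assert f.n_missing == 0


def test_euclidean_field_concentric_spheres():
    inner, outer = icosphere(5.0, 4), icosphere(5.5, 4)
    f = euclidean_field(inner, outer)
    # chordal sag of the faceted spheres bounds the spread around 0.5
    assert f.values.min() == pytest.approx(0.5, abs=0.01)
    assert f.values.max() == pytest.approx(0.5, abs=0.01)


def test_euclidean_field_matches_brute_force(small_mesh_pairs):
    for basis, other in small_mesh_pairs[4:7]:
        f = euclidean_field(basis, other)
        for i in range(0, basis.n_vertices, 37):
            assert f.values[i] == pytest.approx(
                brute_closest_distance(basis.vertices[i], other), abs=1e-9
            )


def test_normal_field_concentric_sign_convention():
    # natural tooth = big sphere, compared model = small sphere, field on
    # the model: positive means the natural surface lies outside
    model, natural = icosphere(5.0, 4), icosphere(5.5, 4)
    f = normal_field(model, natural)
    assert f.n_missing == 0
    assert f.values.min() == pytest.approx(0.5, abs=0.01)
    assert f.values.max() == pytest.approx(0.5, abs=0.01)
    # same geometry with the natural scan as basis: the model is inside,
    # the raw outward value is negative, and flip_sign restores "+ = natural
    # larger"
    g = normal_field(natural, model, flip_sign=True)
    assert np.median(g.values[~g.missing]) == pytest.approx(0.5, abs=0.02)


def test_normal_field_inflation_shifts_by_delta(premolar):
    _, mesh = premolar
    delta = 0.3
    inflated = SurfaceMesh(
        mesh.vertices + delta * mesh.vertex_normals(), mesh.faces
    )
    f = normal_field(mesh, inflated)
    valid = ~f.missing
    assert np.median(f.values[valid]) == pytest.approx(delta, abs=0.05)
    assert (f.values[valid] > 0).mean() > 0.99


def test_euclidean_lower_bounds_normal_magnitude(premolar, molar):
    _, basis = premolar
    rough = RigidTransform.from_axis_angle([0, 1, 0], 1.5, (0.2, -0.1, 0.1))
    other = rough.apply_mesh(basis)
    eu = euclidean_field(basis, other)
    nm = normal_field(basis, other)
    ok = ~nm.missing
    assert (eu.values[ok] <= np.abs(nm.values[ok]) + 1e-9).all()


def test_normal_field_requires_oriented_basis(sphere5):
    flipped = sphere5.flipped()  # inward orientation
    with pytest.raises(GeometryError, match="orient"):
        normal_field(flipped, sphere5)


def test_normal_field_flags_out_of_range_as_missing():
    near = icosphere(1.0, 3)
    far = SurfaceMesh(near.vertices + np.array([0.0, 0.0, 30.0]), near.faces)
    f = normal_field(near, far, max_range=2.0)
    assert f.n_missing > 0
    with pytest.raises(ValueError, match="missing"):
        summarize(DistanceField("x", np.zeros(4), "normal", missing=np.ones(4, bool)))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def test_summarize_hand_cases():
    z = summarize(DistanceField("x", [0.0, 0.0, 0.0], "euclidean"))
    assert z.min == z.max == z.mean == z.median == 0.0

    s = summarize(DistanceField("x", [-1.0, 0.0, 3.0], "normal"))
    assert s.mean == pytest.approx(2 / 3)
    assert s.abs_mean == pytest.approx(4 / 3)
    assert s.median == 0.0 and s.min == -1.0 and s.max == 3.0
    assert s.abs_median == 1.0


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    values=st.lists(
        st.floats(-10, 10, allow_nan=False), min_size=1, max_size=50
    ),
    perm_seed=st.integers(0, 100),
)
def test_summarize_matches_naive_recomputation(values, perm_seed):
    v = np.array(values)
    s = summarize(DistanceField("x", v, "normal"))
    assert s.min == min(values)
    assert s.max == max(values)
    assert s.mean == pytest.approx(sum(values) / len(values), abs=1e-12)
    sv = sorted(values)
    n = len(sv)
    med = sv[n // 2] if n % 2 else (sv[n // 2 - 1] + sv[n // 2]) / 2
    assert s.median == pytest.approx(med, abs=1e-12)
    # permutation invariance (mean up to summation order)
    rng = np.random.default_rng(perm_seed)
    s2 = summarize(DistanceField("x", rng.permutation(v), "normal"))
    assert (s2.min, s2.max, s2.median) == (s.min, s.max, s.median)
    assert s2.mean == pytest.approx(s.mean, abs=1e-12)
    assert s2.abs_mean == pytest.approx(s.abs_mean, abs=1e-12)


def test_summary_invariants_hold(premolar):
    _, mesh = premolar
    other = RigidTransform.from_axis_angle([1, 0, 0], 1.0, (0.1, 0, 0)).apply_mesh(mesh)
    s = summarize(normal_field(mesh, other))
    assert s.min <= s.median <= s.max
    assert s.abs_mean >= abs(s.mean)


# ---------------------------------------------------------------------------
# compare_models
# ---------------------------------------------------------------------------


def test_compare_models_perfect_copy(premolar):
    _, mesh = premolar
    moved = RigidTransform.from_axis_angle([0.3, 1, 0.2], 12.0, (2, -1, 0.5)).apply_mesh(mesh)
    res = compare_models(mesh, moved)
    assert res.euclidean_stats.max < 1e-3
    assert abs(res.normal_stats.mean) < 1e-3


def test_compare_models_basis_selection(premolar):
    _, mesh = premolar
    moved = RigidTransform.from_axis_angle([0, 0, 1], 5.0, (1, 0, 0)).apply_mesh(mesh)
    res_model = compare_models(mesh, moved, basis_choice="model")
    assert res_model.euclidean.basis_mesh_id == "model"
    assert len(res_model.euclidean.values) == moved.n_vertices
    res_nat = compare_models(mesh, moved, basis_choice="natural")
    assert len(res_nat.euclidean.values) == mesh.n_vertices
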