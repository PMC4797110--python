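import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from protshape import (
    SGFConfig,
    TriangleMesh,
    curvature_field,
    icosphere,
    local_cluster,
    sgf_field,
    shape_index,
)
from protshape.curvature import CurvatureField, principal_from_GM


def field_from_principals(k1, k2, boundary=None):
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    kM = 0.5 * (k1 + k2)
    kG = k1 * k2
    if boundary is None:
        boundary = np.zeros(len(k1), dtype=bool)
    return CurvatureField(kG, kM, k1, k2, np.zeros(len(k1), dtype=bool), boundary)


def test_perfect_saddle_gives_zero():
    si = shape_index(field_from_principals([1.0], [-1.0]))
    assert si.si[0] == 0.0


def test_closed_form_value():
    # k1 = 2, k2 = 1: SI = -(2/pi) arctan(3)
    si = shape_index(field_from_principals([2.0], [1.0]))
    assert si.si[0] == pytest.approx(-(2 / np.pi) * np.arctan(3.0))
    assert si.si[0] == pytest.approx(-0.7952, abs=1e-4)


def test_si_bounds_on_random_principals():
    rng = np.random.default_rng(0)
    k1 = rng.normal(size=500) * 3
    k2 = k1 - np.abs(rng.normal(size=500))  # ensure k1 >= k2
    si = shape_index(field_from_principals(k1, k2))
    assert np.all(si.si >= -1) and np.all(si.si <= 1)


def test_umbilic_limits():
    # convex umbilic (kM < 0) -> +1; concave -> -1; flat -> 0
    si = shape_index(field_from_principals([-1.0, 1.0, 1e-12], [-1.0, 1.0, -1e-12]))
    np.testing.assert_array_equal(si.si, [1.0, -1.0, 0.0])


def test_sphere_si_is_exactly_one(sphere4):
    """Convex near-umbilic surface: discretization noise folds into SI = +1."""
    mesh, _ = sphere4
    si = shape_index(curvature_field(mesh))
    np.testing.assert_array_equal(si.si, 1.0)


def test_saddle_center_si_near_zero(saddle41):
    mesh, _ = saddle41
    si = shape_index(curvature_field(mesh))
    center = np.argmin(np.linalg.norm(mesh.vertices[:, :2], axis=1))
    assert abs(si.si[center]) < 0.05


def test_si_rigid_and_scale_invariance(torus_mesh):
    mesh, _ = torus_mesh
    si = shape_index(curvature_field(mesh)).si
    R = Rotation.from_euler("zyx", [1.0, 0.2, -0.7]).as_matrix()
    moved = TriangleMesh(mesh.vertices @ R.T * 3.0 + 1.0, mesh.faces)
    si2 = shape_index(curvature_field(moved)).si
    np.testing.assert_allclose(si2, si, atol=1e-9)


def test_orientation_flip_negates_si(torus_mesh):
    mesh, _ = torus_mesh
    flipped = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1])
    si = shape_index(curvature_field(mesh)).si
    si_f = shape_index(curvature_field(flipped)).si
    np.testing.assert_allclose(si_f, -si, atol=1e-9)


# -- local clusters ---------------------------------------------------------

def test_cluster_depth_zero_is_self(sphere3):
    mesh, _ = sphere3
    assert local_cluster(mesh, 17, 0) == {17}


def test_icosahedron_one_ring():
    mesh, _ = icosphere(1.0, 0)
    for i in range(mesh.n_vertices):
        assert len(local_cluster(mesh, i, 1)) == 6  # valence 5 + itself


def test_deep_cluster_covers_mesh():
    mesh, _ = icosphere(1.0, 1)
    assert local_cluster(mesh, 0, 50) == set(range(mesh.n_vertices))


# -- SGF --------------------------------------------------------------------

def test_sgf_constant_field_is_half_cube(sphere3):
    """Constant SI = c: no extrema, zero variance, area fractions sum to 1."""
    mesh, _ = sphere3
    cf = curvature_field(mesh)
    si = shape_index(cf)
    for c in (1.0, -0.4):
        si.si[:] = c
        sgf = sgf_field(mesh, si)
        np.testing.assert_allclose(sgf.sgf, 0.5 * c**3, rtol=1e-12)


def test_sgf_sphere_is_half(sphere4):
    mesh, _ = sphere4
    si = shape_index(curvature_field(mesh))
    sgf = sgf_field(mesh, si)
    np.testing.assert_allclose(sgf.sgf, 0.5, rtol=1e-12)


def test_sgf_spike_raises_saliency(saddle41):
    """A lone SI spike makes nearby clusters salient (N >= 1, Var > 0)."""
    mesh, _ = saddle41
    n = mesh.n_vertices
    si = shape_index(curvature_field(mesh))
    si.si[:] = 0.0
    spike = 20 * 41 + 20  # grid center
    si.si[spike] = 1.0
    cfg = SGFConfig(ring_depth=2)
    sgf = sgf_field(mesh, si, cfg)
    neighbor = spike + 1
    far = 0
    assert sgf.sgf[neighbor] > sgf.sgf[far]
    assert sgf.sgf[far] == 0.0


def test_sgf_brute_force_small_mesh():
    """Direct transcription of the SGF formula on an icosahedron."""
    mesh, _ = icosphere(1.0, 1)
    cf = curvature_field(mesh)
    si = shape_index(cf)
    rng = np.random.default_rng(5)
    si.si[:] = rng.uniform(-1, 1, mesh.n_vertices)
    cfg = SGFConfig(ring_depth=2)
    out = sgf_field(mesh, si, cfg)

    from protshape import vertex_area
    A = vertex_area(mesh)
    adj = mesh.vertex_adjacency()
    extrema = np.array([
        si.si[j] > si.si[adj[j]].max() or si.si[j] < si.si[adj[j]].min()
        for j in range(mesh.n_vertices)
    ])
    for i in [0, 7, 23]:
        F = sorted(local_cluster(mesh, i, 2))
        frac = A[F] / A[F].sum()
        vals = si.si[F]
        expected = 0.5 * float(frac @ vals**3) + 0.5 * extrema[F].sum() * vals.var()
        assert out.sgf[i] == pytest.approx(expected, rel=1e-12)
        assert out.cluster_sizes[i] == len(F)


def test_sgf_lower_bound_property(torus_mesh):
    """First term >= -w1 (area fractions sum to 1, SI^3 >= -1); second >= 0."""
    mesh, _ = torus_mesh
    si = shape_index(curvature_field(mesh))
    sgf = sgf_field(mesh, si)
    assert np.all(sgf.sgf >= -0.5)


def test_sgf_scale_invariance(torus_mesh):
    mesh, _ = torus_mesh
    si = shape_index(curvature_field(mesh))
    a = sgf_field(mesh, si).sgf
    scaled = TriangleMesh(mesh.vertices * 4.0, mesh.faces)
    si2 = shape_index(curvature_field(scaled))
    b = sgf_field(scaled, si2).sgf
    np.testing.assert_allclose(b, a, atol=1e-9)


def test_orientation_flip_sgf_symmetry():
    """Flipping orientation negates the shape term, keeps the saliency term."""
    mesh, _ = icosphere(1.0, 3)
    mesh_f = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1])
    si = shape_index(curvature_field(mesh))
    si_f = shape_index(curvature_field(mesh_f))
    np.testing.assert_allclose(si_f.si, -si.si, atol=1e-12)
    a = sgf_field(mesh, si).sgf
    b = sgf_field(mesh_f, si_f).sgf
    # both fields constant here (+-1): shape terms are +-0.5, saliency 0
    np.testing.assert_allclose(a + b, 0.0, atol=1e-12)
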