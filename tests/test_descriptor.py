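import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from protshape import (
    DescriptorConfig,
    FeatureVector,
    TriangleMesh,
    build_feature_matrix,
    compute_descriptor,
    feature_vector,
    kmeans_1d,
)
from protshape.descriptor import FeatureMatrix

from oracles import kmeans_1d_optimal_wcss, wcss


def test_kmeans_k_equals_n():
    means = kmeans_1d([1.0, 2.0, 3.0], DescriptorConfig(K=3, seed=0))
    assert sorted(means) == [1.0, 2.0, 3.0]


def test_kmeans_two_blobs():
    rng = np.random.default_rng(42)
    x = np.concatenate([rng.normal(0, 0.1, 50), rng.normal(10, 0.1, 50)])
    means = np.sort(kmeans_1d(x, DescriptorConfig(K=2, seed=1)))
    assert abs(means[0] - 0) < 0.5 and abs(means[1] - 10) < 0.5


def test_kmeans_degenerate_constant_data():
    means = kmeans_1d(np.full(20, 3.5), DescriptorConfig(K=2, seed=0))
    np.testing.assert_allclose(means, 3.5)


def test_kmeans_rejects_too_few_points():
    with pytest.raises(ValueError, match="smaller K"):
        kmeans_1d([1.0, 2.0], DescriptorConfig(K=5))


def test_kmeans_deterministic_under_seed():
    rng = np.random.default_rng(3)
    x = rng.uniform(-1, 1, 500)
    a = kmeans_1d(x, DescriptorConfig(K=16, seed=9))
    b = kmeans_1d(x, DescriptorConfig(K=16, seed=9))
    np.testing.assert_array_equal(a, b)


def test_kmeans_near_optimal_wcss():
    """Lloyd WCSS within 1.05x of the exact DP optimum on 50 seeded instances."""
    specs = []
    for i in range(50):
        rng = np.random.default_rng(1000 + i)
        if i < 40:
            n, K = int(rng.integers(100, 600)), int(rng.integers(3, 17))
        else:
            n, K = 2000, 48
        # SI/SGF-like data: a few components plus background
        parts = [rng.uniform(-1, 1, n // 3)]
        for _ in range(3):
            parts.append(rng.normal(rng.uniform(-1, 1), rng.uniform(0.02, 0.2),
                                    (n - len(parts[0])) // 3 + 1))
        x = np.concatenate(parts)[:n]
        specs.append((x, K, int(rng.integers(0, 2**31))))
    for x, K, seed in specs:
        centers = kmeans_1d(x, DescriptorConfig(K=K, seed=seed))
        achieved = wcss(x, centers)
        optimal = kmeans_1d_optimal_wcss(x, K)
        assert achieved <= 1.05 * optimal + 1e-12


def test_feature_vector_sorted_and_bounded(torus_mesh):
    rng = np.random.default_rng(0)
    si_like = rng.uniform(-1, 1, 2000)
    fv = feature_vector(si_like, "SI", DescriptorConfig(K=48, seed=2))
    assert fv.channel == "SI"
    assert len(fv.values) == 48
    assert np.all(np.diff(fv.values) >= 0)
    assert np.all((fv.values >= -1) & (fv.values <= 1))


def test_feature_vector_constant_field():
    fv = feature_vector(np.full(100, 0.7), "SGF", DescriptorConfig(K=4, seed=0))
    np.testing.assert_allclose(fv.values, 0.7)


def test_feature_matrix_identity_case():
    M = build_feature_matrix(FeatureVector([1.0, 0.0], "SI"),
                             FeatureVector([0.0, 1.0], "SGF")).M
    np.testing.assert_array_equal(M, np.eye(2))


def test_feature_matrix_rank_one_when_p_zero():
    fm = build_feature_matrix(FeatureVector([1.0, 2.0, 3.0], "SI"),
                              FeatureVector([0.0, 0.0, 0.0], "SGF"))
    assert np.linalg.matrix_rank(fm.M) == 1


def test_feature_matrix_psd_rank2():
    rng = np.random.default_rng(11)
    fm = build_feature_matrix(FeatureVector(rng.normal(size=48), "SI"),
                              FeatureVector(rng.normal(size=48), "SGF"))
    np.testing.assert_array_equal(fm.M, fm.M.T)
    evals = np.linalg.eigvalsh(fm.M)
    assert evals.min() > -1e-10
    assert (evals > 1e-10 * evals.max()).sum() <= 2


def test_feature_matrix_length_mismatch():
    with pytest.raises(ValueError):
        build_feature_matrix(FeatureVector([1.0], "SI"), FeatureVector([1.0, 2.0], "SGF"))


def test_descriptor_constant_corollary(sphere4):
    """Exact-SI sphere: T = 1, P = 0.5 so M = 1 + 0.25 everywhere."""
    mesh, _ = sphere4
    fm = compute_descriptor(mesh, cfg=DescriptorConfig(seed=0))
    np.testing.assert_allclose(fm.T.values, 1.0, rtol=1e-12)
    np.testing.assert_allclose(fm.P.values, 0.5, rtol=1e-12)
    np.testing.assert_allclose(fm.M, 1.25, rtol=1e-12)


def test_descriptor_invariances(sphere4):
    """Rigid motion, scaling and re-indexing leave the descriptor unchanged."""
    mesh, _ = sphere4
    cfg = DescriptorConfig(seed=7)
    ref = compute_descriptor(mesh, cfg=cfg).M
    R = Rotation.from_euler("xyz", [0.5, 1.2, -0.3]).as_matrix()
    rng = np.random.default_rng(0)
    perm = rng.permutation(mesh.n_vertices)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    variants = {
        "rotated": TriangleMesh(mesh.vertices @ R.T, mesh.faces, name=mesh.name),
        "translated": TriangleMesh(mesh.vertices + [3.0, -1.0, 2.0], mesh.faces, name=mesh.name),
        "scaled": TriangleMesh(mesh.vertices * 2.0, mesh.faces, name=mesh.name),
        "reindexed": TriangleMesh(mesh.vertices[perm], inv[mesh.faces], name=mesh.name),
    }
    for label, variant in variants.items():
        M = compute_descriptor(variant, cfg=cfg).M
        np.testing.assert_allclose(M, ref, atol=1e-9, err_msg=label)


def test_descriptor_json_roundtrip(sphere3, tmp_path):
    mesh, _ = sphere3
    fm = compute_descriptor(mesh, cfg=DescriptorConfig(K=8, seed=3))
    path = tmp_path / "d.json"
    fm.to_json(path)
    back = FeatureMatrix.from_json(path)
    np.testing.assert_array_equal(back.M, fm.M)
    np.testing.assert_array_equal(back.T.values, fm.T.values)
    assert back.name == fm.name and back.seed == 3
    assert back.mesh_hash == fm.mesh_hash


def test_descriptor_rejects_small_mesh(tetrahedron):
    with pytest.raises(ValueError, match="usable vertices"):
        compute_descriptor(tetrahedron, cfg=DescriptorConfig(K=48))
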