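"""Network building blocks: KNN search, edge features, pattern blocks,
the full forward pass, parameter counting and checkpointing."""

import numpy as np
import pytest

from patternnet.network import (ConfigurationError, NetworkConfig, backward,
                                build_neighbor_features, count_parameters,
                                forward, init_params, knn_graph,
                                load_checkpoint, lp_block, save_checkpoint)
from patternnet.pointcloud_io import LabeledCloud

LRELU = 0.2


# ---------------------------------------------------------------------------
# knn_graph


def test_knn_collinear_example():
    pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [10, 0, 0]])
    nn = knn_graph(pts, K=2)
    assert set(nn[0]) == {1, 2}
    assert list(nn[0]) == [1, 2]  # ascending distance


def test_knn_matches_bruteforce_oracle(rng):
    pts = rng.normal(size=(150, 3))
    k = 7
    nn = knn_graph(pts, k)
    # independent oracle: full pairwise distances, argsort, self excluded
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    expect = np.argsort(d, axis=1)[:, :k]
    np.testing.assert_array_equal(nn, expect)


def test_knn_k_equals_all_others(rng):
    pts = rng.normal(size=(9, 3))
    nn = knn_graph(pts, K=8)
    for i in range(9):
        assert set(nn[i]) == set(range(9)) - {i}


def test_knn_duplicate_point_permutation_stable(rng):
    pts = rng.normal(size=(20, 3))
    pts[11] = pts[3]  # exact duplicate forces a distance tie
    nn = knn_graph(pts, K=5)
    perm = rng.permutation(20)
    nn_p = knn_graph(pts[perm], K=5)
    inv = np.empty(20, dtype=int)
    inv[perm] = np.arange(20)
    for i in range(20):
        a = {tuple(pts[j]) for j in nn[i]}
        b = {tuple(pts[perm][j]) for j in nn_p[inv[i]]}
        assert a == b  # neighbor multisets (as point values) unchanged


def test_knn_too_few_points_raises():
    with pytest.raises(ConfigurationError):
        knn_graph(np.zeros((3, 3)), K=3)


# ---------------------------------------------------------------------------
# build_neighbor_features


def test_neighbor_feature_rows():
    pts = np.array([[0.0, 0, 0], [1, 0, 0]])
    nf = build_neighbor_features(pts, np.array([[1], [0]]))
    np.testing.assert_allclose(nf[0, 0], [0, 0, 0, 1, 0, 0])
    np.testing.assert_allclose(nf[1, 0], [1, 0, 0, -1, 0, 0])


def test_neighbor_features_width_6_for_coords(rng):
    pts = rng.normal(size=(30, 3))
    nf = build_neighbor_features(pts, knn_graph(pts, 4))
    assert nf.shape == (30, 4, 6)


def test_identical_neighbors_zero_edges():
    pts = np.tile([[2.0, 3.0, 4.0]], (4, 1))
    nf = build_neighbor_features(pts, np.array([[1, 2]] * 4))
    np.testing.assert_allclose(nf[..., 3:], 0)


def test_translation_moves_query_half_only(rng):
    pts = rng.normal(size=(5, 3))
    nbrs = knn_graph(pts, 2)
    t = np.array([1.0, -2.0, 0.5])
    nf0 = build_neighbor_features(pts, nbrs)
    nf1 = build_neighbor_features(pts + t, nbrs)
    np.testing.assert_allclose(nf1[..., :3] - nf0[..., :3],
                               np.broadcast_to(t, nf0[..., :3].shape))
    np.testing.assert_allclose(nf1[..., 3:], nf0[..., 3:], atol=1e-12)


# ---------------------------------------------------------------------------
# lp_block


def _block_params(rng, c2, w):
    return {
        "1_W": rng.normal(size=(c2, w)) * 0.3, "1_b": rng.normal(size=w) * 0.1,
        "1_gamma": rng.uniform(0.5, 1.5, w), "1_beta": rng.normal(size=w) * 0.1,
        "1_mean": rng.normal(size=w) * 0.1, "1_var": rng.uniform(0.5, 2.0, w),
        "2_W": rng.normal(size=(w, w)) * 0.3, "2_b": rng.normal(size=w) * 0.1,
        "2_gamma": rng.uniform(0.5, 1.5, w), "2_beta": rng.normal(size=w) * 0.1,
        "2_mean": rng.normal(size=w) * 0.1, "2_var": rng.uniform(0.5, 2.0, w),
    }


def test_lp_block_neighbor_order_invariant(rng):
    nf = rng.normal(size=(6, 5, 8))
    bp = _block_params(rng, 8, 10)
    out = lp_block(nf, bp, width=10)
    shuffled = nf[:, rng.permutation(5), :]
    np.testing.assert_allclose(lp_block(shuffled, bp, width=10), out, atol=1e-12)


def test_lp_block_default_width_32(rng):
    nf = rng.normal(size=(7, 4, 6))
    bp = _block_params(rng, 6, 32)
    assert lp_block(nf, bp, width=32).shape == (7, 32)


def test_lp_block_matches_loop_oracle(rng):
    """Explicit per-row loop + max oracle reproduces the vectorized block."""
    m, k, c2, w = 5, 3, 4, 6
    nf = rng.normal(size=(m, k, c2))
    bp = _block_params(rng, c2, w)
    eps = 1e-5

    def bn(x, layer):
        xh = (x - bp[f"{layer}_mean"]) / np.sqrt(bp[f"{layer}_var"] + eps)
        return bp[f"{layer}_gamma"] * xh + bp[f"{layer}_beta"]

    def lrelu(x):
        return np.where(x > 0, x, LRELU * x)

    expect = np.empty((m, w))
    for q in range(m):
        rows = []
        for j in range(k):
            a1 = lrelu(bn(nf[q, j] @ bp["1_W"] + bp["1_b"], "1"))
            a2 = lrelu(bn(a1 @ bp["2_W"] + bp["2_b"], "2"))
            rows.append(a2)
        expect[q] = np.max(rows, axis=0)
    out = lp_block(nf, bp, width=w)
    np.testing.assert_allclose(out, expect, atol=1e-6)


# ---------------------------------------------------------------------------
# forward


def test_forward_shapes_and_softmax(rng):
    cfg = NetworkConfig(L=2, K=4, lp_widths=(8, 8), global_mlp_widths=(16,),
                        decoder_widths=(12,), num_classes=2)
    cloud = LabeledCloud(rng.normal(size=(40, 3)), np.ones(40, dtype=int))
    params = init_params(cfg, 0)
    res = forward(cloud, cfg, params, partition_seed=1)
    assert res.logits.shape == (40, 2)
    p = np.exp(res.logits) / np.exp(res.logits).sum(axis=1, keepdims=True)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
    assert res.descriptors.psi.shape == (16, 2)
    assert res.descriptors.phi.shape == (16,)


def test_forward_default_config_dimensions(rng):
    cfg = NetworkConfig()  # L=8, K=20, widths 32x4
    cloud = LabeledCloud(rng.normal(size=(512, 3)), np.ones(512, dtype=int))
    params = init_params(cfg, 0)
    res = forward(cloud, cfg, params, partition_seed=0)
    assert res.per_point_features.shape == (512, 128)
    assert res.descriptors.psi.shape == (128, 8)
    assert res.descriptors.phi.shape == (128,)


def test_forward_permutation_equivariance(rng, tiny_net_cfg):
    cloud = LabeledCloud(rng.normal(size=(60, 3)), np.ones(60, dtype=int))
    params = init_params(tiny_net_cfg, 2)
    res = forward(cloud, tiny_net_cfg, params, partition_seed=9)
    perm = rng.permutation(60)
    res_p = forward(LabeledCloud(cloud.coords[perm], cloud.labels[perm]),
                    tiny_net_cfg, params, partition_seed=9)
    np.testing.assert_allclose(res_p.logits, res.logits[perm], atol=1e-5)


def test_forward_deterministic(rng, tiny_net_cfg):
    cloud = LabeledCloud(rng.normal(size=(50, 3)), np.ones(50, dtype=int))
    params = init_params(tiny_net_cfg, 2)
    a = forward(cloud, tiny_net_cfg, params, partition_seed=4)
    b = forward(cloud, tiny_net_cfg, params, partition_seed=4)
    np.testing.assert_array_equal(a.logits, b.logits)


def test_forward_subset_too_small_raises(rng, tiny_net_cfg):
    cloud = LabeledCloud(rng.normal(size=(9, 3)), np.ones(9, dtype=int))
    with pytest.raises(ConfigurationError, match="K"):
        forward(cloud, tiny_net_cfg, init_params(tiny_net_cfg, 0), 0)


# ---------------------------------------------------------------------------
# count_parameters / checkpoints


def test_count_parameters_hand_count_first_block():
    """6->32->32 block with BN on both layers: 1408 scalars."""
    cfg = NetworkConfig(lp_widths=(32,), global_mlp_widths=(32,),
                        decoder_widths=(), num_classes=2, L=2, K=2)
    params = init_params(cfg, 0)
    block = sum(v.size for k, v in params.trainable.items() if k.startswith("lp0_"))
    assert block == (6 * 32 + 32) + (32 * 32 + 32) + 2 * 32 + 2 * 32 == 1408


def test_count_parameters_monotone_in_width():
    big = count_parameters(NetworkConfig())
    small = count_parameters(NetworkConfig.light())
    assert small < big
    assert count_parameters(NetworkConfig()) == sum(
        v.size for v in init_params(NetworkConfig(), 0).trainable.values())


def test_empty_decoder_contributes_nothing():
    with_dec = NetworkConfig(decoder_widths=(10,))
    without = NetworkConfig(decoder_widths=())
    d = with_dec.descriptor_dim
    expected_layer = (3 * d * 10 + 10) + 2 * 10            # dense + BN
    out_diff = (10 * 2 + 2) - (3 * d * 2 + 2)              # out layer fan-in changes
    assert count_parameters(with_dec) - count_parameters(without) == expected_layer + out_diff


def test_checkpoint_roundtrip_lossless(tmp_path, tiny_net_cfg):
    params = init_params(tiny_net_cfg, 5)
    path = tmp_path / "model.npz"
    save_checkpoint(path, tiny_net_cfg, params)
    cfg2, params2 = load_checkpoint(path)
    assert cfg2 == tiny_net_cfg
    for k, v in params.trainable.items():
        np.testing.assert_array_equal(params2.trainable[k], v)
    for k, v in params.running.items():
        np.testing.assert_array_equal(params2.running[k], v)


def test_config_rejects_mismatched_global_width():
    with pytest.raises(ConfigurationError):
        NetworkConfig(lp_widths=(8, 8), global_mlp_widths=(32,))


# ---------------------------------------------------------------------------
# backward (network-level gradient correctness)


def test_backward_matches_finite_differences(rng):
    """Full-network analytic gradients agree with central differences."""
    cfg = NetworkConfig(L=2, K=3, lp_widths=(4, 5), global_mlp_widths=(9,),
                        decoder_widths=(6,), num_classes=2, drop_rate=0.0)
    cloud = LabeledCloud(rng.normal(size=(20, 3)), np.ones(20, dtype=int))
    params = init_params(cfg, 1)
    target = rng.normal(size=(20, 2))

    def loss():
        res = forward(cloud, cfg, params, 7, training=True,
                      dropout_rng=np.random.default_rng(0), want_cache=True)
        return 0.5 * ((res.logits - target) ** 2).sum(), res

    val, res = loss()
    grads = backward(res, res.logits - target)
    eps = 1e-6
    for name in ("lp0_1_W", "lp1_2_gamma", "glob0_W", "dec0_b", "out_W"):
        arr = params.trainable[name]
        for fi in rng.choice(arr.size, size=3, replace=False):
            orig = arr.flat[fi]
            arr.flat[fi] = orig + eps
            lp = loss()[0]
            arr.flat[fi] = orig - eps
            lm = loss()[0]
            arr.flat[fi] = orig
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - grads[name].flat[fi]) < 1e-4 * max(1.0, abs(fd))
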