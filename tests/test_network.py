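"""Encoder blocks, attention, decoders: closed forms and structural contracts."""

import numpy as np
import pytest

from plantseg3d.autodiff import Parameter, Tensor
from plantseg3d.network import (ABLATION_VERSIONS, NetworkConfig,
                                SegmentationNetwork, apply_ablation,
                                attentive_pool, channel_attention,
                                edge_conv_inputs, knn_indices, position_encode,
                                position_encode_graph, spatial_attention)


class TestPositionEncoding:
    def test_unit_offset_neighbor(self):
        r = position_encode((0, 0, 0), [(1, 0, 0)])
        assert r.shape == (1, 10)
        assert np.allclose(r[0], [0, 0, 0, 1, 0, 0, -1, 0, 0, 1])

    def test_self_neighbor_gives_zero_tail(self):
        p = (2.0, -1.0, 0.5)
        r = position_encode(p, [p])
        assert np.allclose(r[0], [*p, *p, 0, 0, 0, 0])

    def test_norm_three_case(self):
        r = position_encode((1, 2, 2), [(0, 0, 0)])
        assert np.allclose(r[0], [1, 2, 2, 0, 0, 0, 1, 2, 2, 3])

    def test_matches_independent_reimplementation(self, rng):
        # independent closed form: concat(p, q, p - q, |p - q|)
        for _ in range(200):
            p, q = rng.normal(size=3), rng.normal(size=3)
            want = np.concatenate([p, q, p - q, [np.sqrt(((p - q) ** 2).sum())]])
            assert np.allclose(position_encode(p, [q])[0], want, atol=1e-12)

    def test_translation_changes_only_absolute_parts(self, rng):
        coords = rng.normal(size=(30, 3))
        idx = knn_indices(coords, 4)
        r1 = position_encode_graph(coords, idx)
        r2 = position_encode_graph(coords + [[10.0, -5.0, 2.0]], idx)
        assert np.allclose(r1[..., 6:], r2[..., 6:], atol=1e-9)   # relative + norm
        assert not np.allclose(r1[..., :3], r2[..., :3])          # absolute p_i


class TestEdgeConv:
    def test_pre_mlp_vector(self):
        f = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
        idx = np.array([[1], [0]])
        out = edge_conv_inputs(f, idx).data
        assert np.allclose(out[0, 0], [1, 0, 1, -1])

    def test_self_neighbor_gives_zero_difference(self):
        f = Tensor(np.array([[3.0, -2.0]]))
        out = edge_conv_inputs(f, np.array([[0]])).data
        assert np.allclose(out[0, 0], [3, -2, 0, 0])

    def test_shared_parameters_are_deterministic(self, rng):
        w = Parameter(rng.normal(size=(8, 5)))
        f = Tensor(rng.normal(size=(12, 4)))
        idx = knn_indices(f.data, 3)
        h1 = (edge_conv_inputs(f, idx).reshape(36, 8) @ w).data
        h2 = (edge_conv_inputs(f, idx).reshape(36, 8) @ w).data
        assert np.array_equal(h1, h2)


class TestAttentivePool:
    def test_constant_scores_equal_mean_pooling(self, rng):
        h = Tensor(rng.normal(size=(10, 6, 4)))
        r = rng.normal(size=(10, 6, 10))
        score_w = Parameter(np.zeros((14, 1)))   # constant scoring function
        out = attentive_pool(h, r, score_w, lambda x: x).data
        mean = np.concatenate([h.data, r], axis=-1).mean(axis=1)
        assert np.allclose(out, mean, atol=1e-14)  # machine precision

    def test_k_equal_one_passes_through(self, rng):
        h = Tensor(rng.normal(size=(5, 1, 3)))
        r = rng.normal(size=(5, 1, 10))
        score_w = Parameter(rng.normal(size=(13, 1)))
        out = attentive_pool(h, r, score_w, lambda x: x).data
        assert np.allclose(out, np.concatenate([h.data, r], -1)[:, 0, :])

    def test_identical_neighbors_make_weights_irrelevant(self, rng):
        one = rng.normal(size=(1, 1, 5))
        h = Tensor(np.repeat(one, 7, axis=1))
        r = np.repeat(rng.normal(size=(1, 1, 10)), 7, axis=1)
        score_w = Parameter(rng.normal(size=(15, 1)))
        out = attentive_pool(h, r, score_w, lambda x: x).data
        assert np.allclose(out[0], np.concatenate([one[0, 0], r[0, 0]]))


class TestAttention:
    def test_spatial_attention_zeros_stay_zero(self):
        out = spatial_attention(Tensor(np.zeros((6, 4)))).data
        assert np.allclose(out, 0.0)

    def test_spatial_attention_rows_independent(self, rng):
        F = rng.normal(size=(8, 5))
        out1 = spatial_attention(Tensor(F)).data
        F2 = F.copy()
        F2[3] *= 10
        out2 = spatial_attention(Tensor(F2)).data
        mask = np.arange(8) != 3
        assert np.allclose(out1[mask], out2[mask])
        assert not np.allclose(out1[3], out2[3])

    def test_channel_attention_identity_conv_closed_form(self, rng):
        F = rng.normal(size=(9, 4))
        eye = Parameter(np.eye(4))
        zero = Parameter(np.zeros(4))
        out = channel_attention(Tensor(F), eye, zero, eye, zero).data
        gate = 1 / (1 + np.exp(-(F.mean(axis=0) + F.max(axis=0))))
        assert np.allclose(out, F * gate, atol=1e-12)
        assert np.all((gate > 0) & (gate < 1))

    def test_channel_attention_zeros_stay_zero(self):
        eye, zero = Parameter(np.eye(3)), Parameter(np.zeros(3))
        out = channel_attention(Tensor(np.zeros((5, 3))), eye, zero, eye, zero)
        assert np.allclose(out.data, 0.0)


class TestForward:
    def test_output_shapes(self, toy_config, rng):
        net = SegmentationNetwork(toy_config, seed=0)
        coords = rng.normal(size=(512, 3))
        out = net.forward(coords, seed=0)
        assert out.sem_logits.shape == (512, 6)
        assert out.ins_embed.shape == (512, 5)
        assert out.fused.shape == (512, 32)
        assert np.all(np.isfinite(out.sem_logits.data))
        assert np.all(out.fused.data >= 0)  # fused map is post-ReLU

    def test_wrong_cloud_size_rejected(self, toy_config, rng):
        net = SegmentationNetwork(toy_config, seed=0)
        with pytest.raises(ValueError, match="expected"):
            net.forward(rng.normal(size=(100, 3)))

    def test_encoder_levels_form_subset_chain(self, toy_config, rng):
        net = SegmentationNetwork(toy_config, seed=0)
        plan = net.prepare(rng.normal(size=(512, 3)), seed=0)
        sizes = [len(c) for c in plan.level_coords]
        assert sizes == [128, 64, 32, 16]
        # each level's coords are rows of the previous level
        prev = plan.coords
        for lvl, idx in zip(plan.level_coords, plan.level_index):
            assert np.array_equal(prev[idx], lvl)
            prev = lvl

    def test_forward_is_deterministic(self, toy_config, rng):
        net = SegmentationNetwork(toy_config, seed=0)
        coords = rng.normal(size=(512, 3))
        a = net.forward(coords, seed=0)
        b = net.forward(coords, seed=0)
        assert np.array_equal(a.sem_logits.data, b.sem_logits.data)
        assert np.array_equal(a.ins_embed.data, b.ins_embed.data)

    def test_permutation_equivariance(self, tiny_network, rng):
        coords = rng.normal(size=(20, 3))
        perm = rng.permutation(20)
        a = tiny_network.forward(coords, seed=3)
        b = tiny_network.forward(coords[perm], seed=3)
        assert np.allclose(a.sem_logits.data[perm], b.sem_logits.data, atol=1e-9)
        assert np.allclose(a.ins_embed.data[perm], b.ins_embed.data, atol=1e-9)

    def test_every_parameter_gets_gradient(self, tiny_network, rng):
        from plantseg3d.losses import total_loss

        coords = rng.normal(size=(20, 3))
        sem = rng.integers(0, 6, 20)
        ins = rng.integers(0, 3, 20)
        tiny_network.zero_grad()
        out = tiny_network.forward(coords, seed=1)
        loss, _ = total_loss(out, sem, ins)
        loss.backward()
        dead = [k for k, p in tiny_network.params.items()
                if p.grad is None or np.abs(p.grad).max() == 0]
        assert dead == []

    def test_checkpoint_roundtrip(self, tiny_network, tmp_path, rng):
        from plantseg3d.train import load_checkpoint, save_checkpoint

        coords = rng.normal(size=(20, 3))
        ref = tiny_network.forward(coords, seed=0).sem_logits.data
        path = tmp_path / "ck.npz"
        save_checkpoint(path, tiny_network)
        net2, meta, _ = load_checkpoint(path)
        assert np.array_equal(net2.forward(coords, seed=0).sem_logits.data, ref)


class TestAblations:
    @pytest.mark.parametrize("version", sorted(ABLATION_VERSIONS))
    def test_versions_run_and_preserve_parameter_count(self, version, toy_config, rng):
        full = SegmentationNetwork(toy_config, seed=0).parameter_count()
        cfg = apply_ablation(toy_config, version)
        net = SegmentationNetwork(cfg, seed=0)
        assert abs(net.parameter_count() - full) / full < 0.10
        out = net.forward(rng.normal(size=(512, 3)), seed=0)
        assert out.sem_logits.shape == (512, 6)
        assert np.all(np.isfinite(out.sem_logits.data))

    def test_unknown_version_rejected(self, toy_config):
        with pytest.raises(ValueError, match="unknown ablation"):
            apply_ablation(toy_config, "A9")

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            NetworkConfig(level_points=(128, 128, 64, 32))
        with pytest.raises(ValueError, match="neighborhood"):
            NetworkConfig(n_points=512, level_points=(128, 64, 32, 8),
                          k_schedule=(16, 16, 8, 16))
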