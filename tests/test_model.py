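"""Network components against brute-force oracles and analytic limits."""

import numpy as np
import pytest

from eegfusion.autograd import Tensor
from eegfusion.model import (
    AttentionConfig,
    ChannelAttention,
    ClassifierHead,
    ClassProbabilities,
    CnnBranch,
    DualBranchModel,
    FeatureFilter,
    ModelConfig,
    MultiHeadAttention,
    PatchEmbed,
    SpatialAttention,
    ViTBranch,
    cross_entropy,
    fuse_features,
)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# patch embedding
# ---------------------------------------------------------------------------

class TestPatchEmbed:
    def test_token_count_19x1000_patch100(self, rng):
        cfg = AttentionConfig(n_heads=4, patch_len=100, embed_dim=128)
        pe = PatchEmbed(cfg, rng)
        out = pe(Tensor(rng.standard_normal((1, 19, 1000))))
        assert out.shape == (1, 190, 128)  # 19 channels x 10 patches

    def test_identity_projection_returns_flattened_patch(self, rng):
        cfg = AttentionConfig(n_heads=1, patch_len=6, embed_dim=6)
        pe = PatchEmbed(cfg, rng)
        pe.proj.weight.data = np.eye(6)
        pe.proj.bias.data = np.zeros(6)
        row = rng.standard_normal((1, 1, 6))
        out = pe(Tensor(row))
        np.testing.assert_allclose(out.data[0, 0], row[0, 0])

    def test_zero_input_zero_bias_gives_zero_tokens(self, rng):
        cfg = AttentionConfig(n_heads=1, patch_len=5, embed_dim=5)
        pe = PatchEmbed(cfg, rng)
        pe.proj.bias.data = np.zeros(5)
        out = pe(Tensor(np.zeros((2, 3, 10))))
        np.testing.assert_array_equal(out.data, 0)

    def test_non_divisible_patch_length_rejected(self, rng):
        cfg = AttentionConfig(n_heads=1, patch_len=7, embed_dim=7)
        pe = PatchEmbed(cfg, rng)
        with pytest.raises(ValueError, match="does not divide"):
            pe(Tensor(np.zeros((1, 2, 10))))


# ---------------------------------------------------------------------------
# multi-head attention
# ---------------------------------------------------------------------------

def naive_mha(q, k, v, mha: MultiHeadAttention) -> np.ndarray:
    """Brute-force dense attention using the module's own projections."""
    Q = q @ mha.wq.weight.data
    K = k @ mha.wk.weight.data
    V = v @ mha.wv.weight.data
    h, dh = mha.cfg.n_heads, mha.cfg.head_dim
    heads = []
    for j in range(h):
        Qh, Kh, Vh = (M[:, j * dh:(j + 1) * dh] for M in (Q, K, V))
        scores = Qh @ Kh.T / np.sqrt(dh)
        w = np.exp(scores - scores.max(axis=1, keepdims=True))
        w = w / w.sum(axis=1, keepdims=True)
        heads.append(w @ Vh)
    return np.concatenate(heads, axis=1) @ mha.wo.weight.data


class TestMultiHeadAttention:
    def test_single_key_identity_projections_returns_value(self, rng):
        cfg = AttentionConfig(n_heads=1, patch_len=4, embed_dim=4)
        mha = MultiHeadAttention(cfg, rng)
        for lin in (mha.wq, mha.wk, mha.wv, mha.wo):
            lin.weight.data = np.eye(4)
        token = rng.standard_normal((1, 1, 4))
        out = mha(Tensor(rng.standard_normal((1, 3, 4))), Tensor(token), Tensor(token))
        np.testing.assert_allclose(out.data, np.broadcast_to(token, (1, 3, 4)))

    def test_attention_rows_sum_to_one(self, rng):
        cfg = AttentionConfig(n_heads=2, patch_len=4, embed_dim=8)
        mha = MultiHeadAttention(cfg, rng)
        q = Tensor(rng.standard_normal((2, 5, 8)))
        k = Tensor(rng.standard_normal((2, 3, 8)))
        weights = mha.attention_weights(q, k)
        np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(weights >= 0)

    @pytest.mark.parametrize("n_tokens,n_heads", [(2, 1), (2, 2), (5, 2), (4, 4)])
    def test_matches_brute_force_oracle(self, rng, n_tokens, n_heads):
        cfg = AttentionConfig(n_heads=n_heads, patch_len=4, embed_dim=8)
        mha = MultiHeadAttention(cfg, rng)
        q = rng.standard_normal((n_tokens, 8))
        out = mha(Tensor(q[None]), Tensor(q[None]), Tensor(q[None])).data[0]
        np.testing.assert_allclose(out, naive_mha(q, q, q, mha), atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        cfg = AttentionConfig(n_heads=1, patch_len=4, embed_dim=4)
        mha = MultiHeadAttention(cfg, rng)
        with pytest.raises(ValueError):
            mha(Tensor(np.zeros((1, 2, 4))), Tensor(np.zeros((1, 2, 3))),
                Tensor(np.zeros((1, 2, 3))))


# ---------------------------------------------------------------------------
# branches and fusion
# ---------------------------------------------------------------------------

class TestBranches:
    def test_vit_branch_emits_19_by_128_at_defaults(self, rng):
        model_cfg = ModelConfig()
        branch = ViTBranch(model_cfg, window_samples=1000, rng=rng)
        out = branch(Tensor(rng.standard_normal((1, 19, 1000))))
        assert out.shape == (1, 19, 128)

    def test_cnn_branch_emits_19_by_128_at_defaults(self, rng):
        model_cfg = ModelConfig(cnn_time_downsample=10)
        branch = CnnBranch(model_cfg, rng)
        out = branch(Tensor(rng.standard_normal((1, 5, 19, 10000))))
        assert out.shape == (1, 19, 128)

    def test_vit_deterministic_in_eval(self, small_model_config, rng):
        branch = ViTBranch(small_model_config, window_samples=200, rng=rng)
        x = rng.standard_normal((1, 19, 200))
        np.testing.assert_array_equal(branch(Tensor(x)).data, branch(Tensor(x)).data)

    def test_vit_channel_permutation_equivariance(self, small_model_config, rng):
        branch = ViTBranch(small_model_config, window_samples=200, rng=rng)
        x = rng.standard_normal((1, 19, 200))
        perm = rng.permutation(19)
        out = branch(Tensor(x)).data
        out_perm = branch(Tensor(x[:, perm, :])).data
        np.testing.assert_allclose(out_perm, out[:, perm, :], atol=1e-10)

    def test_cnn_zero_input_zero_bias_gives_zero(self, small_model_config, rng):
        branch = CnnBranch(small_model_config, rng)
        for conv in branch.convs:
            conv.bias.data[:] = 0
        branch.out_proj.bias.data[:] = 0
        out = branch(Tensor(np.zeros((1, 5, 19, 400))))
        np.testing.assert_allclose(out.data, 0, atol=1e-12)

    def test_cnn_wrong_band_count_rejected(self, small_model_config, rng):
        branch = CnnBranch(small_model_config, rng)
        with pytest.raises(ValueError, match="band"):
            branch(Tensor(np.zeros((1, 4, 19, 400))))


class TestFusion:
    def test_dual_128_maps_fuse_to_256(self, rng):
        a = rng.standard_normal((1, 19, 128))
        b = rng.standard_normal((1, 19, 128))
        assert fuse_features(a, b).shape == (1, 19, 256)

    def test_vit_block_occupies_leading_channels(self, rng):
        a = rng.standard_normal((1, 19, 128))
        fused = fuse_features(a, np.zeros((1, 19, 128))).data
        np.testing.assert_array_equal(fused[..., :128], a)
        np.testing.assert_array_equal(fused[..., 128:], 0)

    def test_fusion_is_lossless(self, rng):
        a, b = rng.standard_normal((2, 1, 19, 128))
        fused = fuse_features(a, b).data
        np.testing.assert_array_equal(fused[..., :128], a)
        np.testing.assert_array_equal(fused[..., 128:], b)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fuse_features(np.zeros((1, 19, 128)), np.zeros((1, 18, 128)))


# ---------------------------------------------------------------------------
# feature filter (channel + spatial attention)
# ---------------------------------------------------------------------------

def naive_channel_attention(fmap, ca: ChannelAttention) -> np.ndarray:
    """Direct evaluation of sigmoid(MLP(avgpool) + MLP(maxpool))."""
    def mlp(x):
        h = np.maximum(0.0, x @ ca.fc1.weight.data + ca.fc1.bias.data)
        return h @ ca.fc2.weight.data + ca.fc2.bias.data

    avg = fmap.mean(axis=(2, 3))
    mx = fmap.max(axis=(2, 3))
    return sigmoid(mlp(avg) + mlp(mx))


def naive_spatial_attention(fmap, sa: SpatialAttention) -> np.ndarray:
    """Direct zero-padded 2-D convolution of the stacked avg/max planes."""
    B, C, H, W = fmap.shape
    planes = np.stack([fmap.mean(axis=1), fmap.max(axis=1)], axis=1)
    kern = sa.conv.weight.data[0]  # (2, k, k)
    bias = sa.conv.bias.data[0]
    k = kern.shape[-1]
    pad = k // 2
    padded = np.pad(planes, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((B, 1, H, W))
    for b in range(B):
        for i in range(H):
            for j in range(W):
                acc = bias
                for c in range(2):
                    for u in range(k):
                        for v in range(k):
                            acc += kern[c, u, v] * padded[b, c, i + u, j + v]
                out[b, 0, i, j] = acc
    return sigmoid(out)


class TestChannelAttention:
    def test_zero_input_zero_bias_gives_half(self, rng):
        ca = ChannelAttention(8, rng, reduction=2)
        out = ca(Tensor(np.zeros((1, 8, 4, 4)))).data
        np.testing.assert_allclose(out, 0.5)

    def test_spatially_constant_input_doubles_mlp(self, rng):
        ca = ChannelAttention(6, rng, reduction=2)
        const = rng.standard_normal((1, 6))
        fmap = np.broadcast_to(const[:, :, None, None], (1, 6, 3, 5)).copy()
        out = ca(Tensor(fmap)).data

        def mlp(x):
            h = np.maximum(0.0, x @ ca.fc1.weight.data + ca.fc1.bias.data)
            return h @ ca.fc2.weight.data + ca.fc2.bias.data

        np.testing.assert_allclose(out, sigmoid(2 * mlp(const)), atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        ca = ChannelAttention(8, rng, reduction=4)
        fmap = rng.standard_normal((2, 8, 4, 4))
        np.testing.assert_allclose(
            ca(Tensor(fmap)).data, naive_channel_attention(fmap, ca), atol=1e-12
        )

    def test_weights_strictly_inside_unit_interval(self, rng):
        ca = ChannelAttention(8, rng)
        out = ca(Tensor(rng.standard_normal((3, 8, 2, 2)))).data
        assert np.all((out > 0) & (out < 1))


class TestSpatialAttention:
    def test_zero_input_zero_bias_gives_uniform_half(self, rng):
        sa = SpatialAttention(rng, kernel=7)
        sa.conv.bias.data[:] = 0
        out = sa(Tensor(np.zeros((1, 4, 19, 1)))).data
        np.testing.assert_allclose(out, 0.5)

    @pytest.mark.parametrize("shape", [(1, 3, 5, 5), (2, 4, 19, 1), (1, 2, 1, 1)])
    def test_output_preserves_spatial_shape(self, rng, shape):
        sa = SpatialAttention(rng, kernel=7)
        out = sa(Tensor(np.zeros(shape))).data
        assert out.shape == (shape[0], 1, shape[2], shape[3])

    def test_matches_brute_force_convolution_oracle(self, rng):
        sa = SpatialAttention(rng, kernel=7)
        fmap = rng.standard_normal((1, 3, 5, 5))
        np.testing.assert_allclose(
            sa(Tensor(fmap)).data, naive_spatial_attention(fmap, sa), atol=1e-12
        )

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            SpatialAttention(rng, kernel=6)


class TestFeatureFilter:
    def test_composition_matches_elementwise_product(self, rng):
        ff = FeatureFilter(16, rng, reduction=4, kernel=7)
        fused = rng.standard_normal((2, 19, 16))
        fmap = fused.transpose(0, 2, 1)[:, :, :, None]
        mc = ff.channel(Tensor(fmap)).data[:, :, None, None]
        f1 = fmap * mc
        ms = ff.spatial(Tensor(f1)).data
        expected = (f1 * ms)[:, :, :, 0].transpose(0, 2, 1)
        np.testing.assert_allclose(ff(Tensor(fused)).data, expected, atol=1e-12)

    def test_unit_weights_give_identity(self, rng):
        ff = FeatureFilter(8, rng)
        ff.channel = lambda f: Tensor(np.ones((f.shape[0], f.shape[1])))
        ff.spatial = lambda f: Tensor(np.ones((f.shape[0], 1, f.shape[2], f.shape[3])))
        fused = rng.standard_normal((1, 19, 8))
        np.testing.assert_allclose(ff(Tensor(fused)).data, fused, atol=1e-12)

    def test_zero_input_gives_zero_output(self, rng):
        ff = FeatureFilter(8, rng)
        out = ff(Tensor(np.zeros((1, 19, 8)))).data
        np.testing.assert_array_equal(out, 0)

    def test_filter_is_a_contraction(self, rng):
        ff = FeatureFilter(16, rng)
        fused = rng.standard_normal((2, 19, 16))
        out = ff(Tensor(fused)).data
        assert np.all(np.abs(out) <= np.abs(fused) + 1e-12)


# ---------------------------------------------------------------------------
# classifier and loss
# ---------------------------------------------------------------------------

class TestClassifier:
    def test_zero_input_zero_bias_uniform_probabilities(self, rng):
        head = ClassifierHead(19 * 8, rng, hidden=4)
        logits = head(Tensor(np.zeros((1, 19, 8)))).data
        e = np.exp(logits)
        np.testing.assert_allclose(e / e.sum(), 1 / 3, atol=1e-12)

    def test_model_probabilities_form_simplex(self, small_model_config, rng):
        model = DualBranchModel(small_model_config, window_samples=200, seed=0)
        segs = rng.standard_normal((3, 19, 200))
        bands = rng.standard_normal((3, 5, 19, 400))
        probs = model.predict_proba(segs, bands)
        assert probs.shape == (3, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(probs >= 0)

    def test_class_probabilities_validation(self):
        with pytest.raises(ValueError):
            ClassProbabilities(np.array([0.5, 0.6, 0.2]))
        assert ClassProbabilities(np.array([0.1, 0.1, 0.8])).hard_label == 2


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        assert cross_entropy(np.array([[1.0, 0.0, 0.0]]), [0]) == pytest.approx(0, abs=1e-9)

    def test_uniform_prediction_is_log3(self):
        probs = np.full((4, 3), 1 / 3)
        assert cross_entropy(probs, [0, 1, 2, 0]) == pytest.approx(np.log(3), abs=1e-9)

    def test_hand_computed_batch_mean(self):
        probs = np.array([[0.7, 0.2, 0.1], [0.25, 0.5, 0.25]])
        expected = np.mean([-np.log(0.7), -np.log(0.5)])
        assert cross_entropy(probs, [0, 1]) == pytest.approx(expected, abs=1e-9)

    def test_zero_probability_clamped_not_infinite(self):
        loss = cross_entropy(np.array([[0.0, 1.0, 0.0]]), [0])
        assert np.isfinite(loss) and loss > 0

    def test_batch_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.full((2, 3), 1 / 3), [0])


# ---------------------------------------------------------------------------
# whole model
# ---------------------------------------------------------------------------

class TestDualBranchModel:
    def test_eval_forward_deterministic(self, small_model_config, rng):
        model = DualBranchModel(small_model_config, window_samples=200, seed=1)
        segs = rng.standard_normal((2, 19, 200))
        bands = rng.standard_normal((2, 5, 19, 400))
        np.testing.assert_array_equal(
            model.predict_proba(segs, bands), model.predict_proba(segs, bands)
        )

    @pytest.mark.parametrize("variant,n_branches", [
        ("cnn_only", 1), ("vit_only", 1), ("cnn_cnn", 2), ("vit_vit", 2),
        ("vit_cnn", 2),
    ])
    def test_branch_variants_build_and_run(self, small_model_config, rng,
                                           variant, n_branches):
        cfg = ModelConfig(**{**small_model_config.to_dict(), "branches": variant})
        model = DualBranchModel(cfg, window_samples=200, seed=0)
        assert len(model.branch_modules) == n_branches
        probs = model.predict_proba(
            rng.standard_normal((1, 19, 200)), rng.standard_normal((1, 5, 19, 400))
        )
        np.testing.assert_allclose(probs.sum(), 1.0, atol=1e-9)

    def test_filter_off_skips_attention(self, small_model_config):
        cfg = ModelConfig(**{**small_model_config.to_dict(), "use_filter": False})
        model = DualBranchModel(cfg, window_samples=200, seed=0)
        assert model.filter is None

    def test_checkpoint_round_trip(self, small_model_config, rng, tmp_path):
        model = DualBranchModel(small_model_config, window_samples=200, seed=2)
        segs = rng.standard_normal((1, 19, 200))
        bands = rng.standard_normal((1, 5, 19, 400))
        before = model.predict_proba(segs, bands)
        model.save(tmp_path / "ckpt.npz")
        restored = DualBranchModel.load(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(before, restored.predict_proba(segs, bands))
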