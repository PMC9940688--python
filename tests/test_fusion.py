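"""Attention-selection algebra, eigen smoothing, and the fusion network."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from camfuse import (
    FeatureStack,
    FusionConfig,
    FusionNet,
    ImportanceMap,
    attention_rec,
    eigen_smooth,
    extract_features,
    fuse_cams,
    reconstruct,
)
from camfuse.fusion import FusedStack


def maps_from(arrays, sources=("cnn", "vit", "swin")):
    return [ImportanceMap(values=a, source=s) for a, s in zip(arrays, sources)]


def minmax_oracle(stack, w0, w1):
    """Independent double-loop min/max selection."""
    n, k, u, v = stack.shape
    out = np.zeros((k, u, v))
    for kk in range(k):
        for i in range(u):
            for j in range(v):
                vals = [stack[m, kk, i, j] for m in range(n)]
                inter, union = min(vals), max(vals)
                out[kk, i, j] = w0 * inter + w1 * (union - inter)
    return out


class TestAttentionRec:
    def test_consensus_reduces_to_w0_alpha(self, rng):
        alpha = rng.uniform(size=(2, 5, 5))
        stack = FeatureStack(np.stack([alpha, alpha, alpha]), normalized=True)
        cfg = FusionConfig(w0=0.9, w1=0.3, eigen=False)
        fused = attention_rec(stack, cfg)
        np.testing.assert_allclose(fused.maps, 0.9 * alpha)

    def test_two_by_two_hand_oracle(self):
        a1 = np.array([[1.0, 0.0], [0.0, 0.0]])
        a2 = np.array([[1.0, 1.0], [0.0, 0.0]])
        a3 = np.array([[1.0, 0.0], [1.0, 0.0]])
        stack = FeatureStack(np.stack([a1, a2, a3])[:, None], normalized=True)
        fused = attention_rec(stack, FusionConfig(w0=1.0, w1=0.5, eigen=False))
        np.testing.assert_allclose(fused.maps[0], [[1.0, 0.5], [0.5, 0.0]])

    def test_all_zero_stack_stays_zero(self):
        stack = FeatureStack(np.zeros((3, 2, 4, 4)), normalized=True)
        fused = attention_rec(stack, FusionConfig())
        np.testing.assert_array_equal(fused.maps, np.zeros((2, 4, 4)))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_minmax_oracle(self, seed):
        r = np.random.default_rng(seed)
        stack = r.uniform(size=(3, 2, 4, 4))
        cfg = FusionConfig(w0=1.0, w1=0.5, eigen=False)
        fused = attention_rec(FeatureStack(stack, normalized=True), cfg)
        np.testing.assert_allclose(
            fused.maps, minmax_oracle(stack, cfg.w0, cfg.w1), atol=1e-9
        )

    def test_bounds_zero_to_w0(self, rng):
        stack = rng.uniform(size=(3, 4, 8, 8))
        for w0, w1 in [(1.0, 0.5), (0.7, 0.7), (2.0, 0.0)]:
            fused = attention_rec(
                FeatureStack(stack, normalized=True), FusionConfig(w0=w0, w1=w1, eigen=False)
            )
            assert fused.maps.min() >= 0.0 and fused.maps.max() <= w0 + 1e-12

    def test_permutation_invariance(self, rng):
        stack = rng.uniform(size=(3, 2, 5, 5))
        cfg = FusionConfig(eigen=False)
        base = attention_rec(FeatureStack(stack, normalized=True), cfg).maps
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            permuted = attention_rec(
                FeatureStack(stack[list(perm)], normalized=True), cfg
            ).maps
            np.testing.assert_array_equal(base, permuted)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6), st.integers(0, 2), st.integers(0, 15))
    def test_pixelwise_monotonicity(self, seed, view, pixel):
        # raising one pixel of one input never lowers the fused value there
        r = np.random.default_rng(seed)
        stack = r.uniform(low=0.0, high=0.9, size=(3, 1, 4, 4))
        i, j = divmod(pixel, 4)
        cfg = FusionConfig(eigen=False)
        lo = attention_rec(FeatureStack(stack, normalized=True), cfg).maps[0, i, j]
        stack2 = stack.copy()
        stack2[view, 0, i, j] += 0.1
        hi = attention_rec(FeatureStack(stack2, normalized=True), cfg).maps[0, i, j]
        assert hi >= lo - 1e-12

    def test_unnormalized_stack_rejected(self, rng):
        stack = FeatureStack(rng.normal(size=(3, 1, 4, 4)), normalized=False)
        with pytest.raises(ValueError):
            attention_rec(stack, FusionConfig())


class TestEigenSmooth:
    def eigh_rank1_oracle(self, x):
        """Independent rank-1 reconstruction via the eigendecomposition of
        the Gram matrix (not the SVD route the implementation takes)."""
        k = x.shape[0]
        flat = x.reshape(k, -1)
        gram = flat @ flat.T
        w, vecs = np.linalg.eigh(gram)
        u1 = vecs[:, -1]
        v1 = flat.T @ u1
        norm = np.linalg.norm(v1)
        if norm == 0:
            return np.zeros_like(x)
        rec = np.outer(u1, v1)
        return rec.reshape(x.shape)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_rank1_oracle(self, seed):
        x = np.random.default_rng(seed).uniform(size=(4, 8, 8))
        expected = np.maximum(self.eigh_rank1_oracle(x), 0.0)
        np.testing.assert_allclose(eigen_smooth(x), expected, atol=1e-6)

    def test_rank_one_stack_is_fixed_point(self, rng):
        base = rng.uniform(size=(6, 6))
        stack = np.stack([c * base for c in (0.5, 1.0, 2.0)])
        np.testing.assert_allclose(eigen_smooth(stack), stack, atol=1e-6)

    def test_constant_stack_stays_constant(self):
        stack = np.full((3, 4, 4), 0.4)
        np.testing.assert_allclose(eigen_smooth(stack), stack, atol=1e-9)


class TestFusionNetwork:
    def test_identical_inputs_identical_features(self, rng):
        m = ImportanceMap(rng.uniform(size=(16, 16)), "cnn")
        maps = [ImportanceMap(m.values.copy(), s) for s in ("cnn", "vit", "swin")]
        cfg = FusionConfig(seed=3)
        stack = extract_features(maps, cfg, FusionNet(cfg))
        np.testing.assert_array_equal(stack.maps[0], stack.maps[1])
        np.testing.assert_array_equal(stack.maps[1], stack.maps[2])

    def test_all_zero_maps_all_zero_features(self):
        maps = maps_from([np.zeros((8, 8))] * 3)
        cfg = FusionConfig(seed=0)
        stack = extract_features(maps, cfg, FusionNet(cfg))
        np.testing.assert_array_equal(stack.maps, np.zeros_like(stack.maps))

    def test_fixed_seed_bit_identical(self, rng):
        maps = maps_from(list(rng.uniform(size=(3, 12, 12))))
        cfg = FusionConfig(seed=11)
        a = fuse_cams(maps, cfg, mode="network").values
        b = fuse_cams(maps, cfg, mode="network").values
        np.testing.assert_array_equal(a, b)

    def test_reconstruct_always_three_channels(self, rng):
        cfg = FusionConfig(seed=1)
        net = FusionNet(cfg)
        fused = FusedStack(rng.uniform(size=(cfg.conv_channels[1], 6, 6)))
        assert reconstruct(fused, cfg, net).shape == (3, 6, 6)

    def test_reconstruct_zero_input_zero_output(self):
        cfg = FusionConfig(seed=2)
        fused = FusedStack(np.zeros((cfg.conv_channels[1], 5, 5)))
        np.testing.assert_array_equal(
            reconstruct(fused, cfg, FusionNet(cfg)), np.zeros((3, 5, 5))
        )

    def test_network_mode_permutation_invariant(self, rng):
        arrays = list(rng.uniform(size=(3, 10, 10)))
        cfg = FusionConfig(seed=5)
        net = FusionNet(cfg)
        a = fuse_cams(maps_from(arrays), cfg, mode="network", net=net).values
        reordered = maps_from([arrays[2], arrays[0], arrays[1]],
                              sources=("swin", "cnn", "vit"))
        b = fuse_cams(reordered, cfg, mode="network", net=net).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_weight_archive_round_trip(self, tmp_path, rng):
        cfg = FusionConfig(seed=4)
        a = FusionNet(cfg)
        a.save_weights(tmp_path / "fnet.npz")
        b = FusionNet(FusionConfig(seed=99))
        b.load_weights(tmp_path / "fnet.npz")
        maps = maps_from(list(rng.uniform(size=(3, 8, 8))))
        np.testing.assert_array_equal(
            fuse_cams(maps, cfg, mode="network", net=a).values,
            fuse_cams(maps, cfg, mode="network", net=b).values,
        )


class TestFuseMaps:
    def test_identical_cams_identity_map_level(self, rng):
        values = rng.uniform(size=(9, 9))
        values = (values - values.min()) / (values.max() - values.min())
        maps = maps_from([values.copy()] * 3)
        fused = fuse_cams(maps, FusionConfig(w0=1.0, eigen=False), mode="map")
        np.testing.assert_allclose(fused.values, values, atol=1e-12)

    def test_map_level_two_by_two_oracle(self):
        maps = maps_from([
            np.array([[1.0, 0.0], [0.0, 0.0]]),
            np.array([[1.0, 1.0], [0.0, 0.0]]),
            np.array([[1.0, 0.0], [1.0, 0.0]]),
        ])
        fused = fuse_cams(maps, FusionConfig(w0=1.0, w1=0.5, eigen=False), mode="map")
        np.testing.assert_allclose(fused.values, [[1.0, 0.5], [0.5, 0.0]])

    def test_wrong_map_count_rejected(self, rng):
        maps = maps_from(list(rng.uniform(size=(2, 4, 4))))
        with pytest.raises(ValueError):
            fuse_cams(maps, FusionConfig())

    def test_shape_mismatch_rejected(self):
        maps = [
            ImportanceMap(np.zeros((4, 4)), "cnn"),
            ImportanceMap(np.zeros((5, 5)), "vit"),
            ImportanceMap(np.zeros((4, 4)), "swin"),
        ]
        with pytest.raises(ValueError):
            fuse_cams(maps, FusionConfig())

    def test_invalid_weight_order_rejected(self):
        with pytest.raises(ValueError):
            FusionConfig(w0=0.2, w1=0.5)
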