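"""Backbone contracts: geometry of the CAM target layer, patch
transformation reversibility, and the gradient of the class score."""

import numpy as np
import pytest

from camfuse import (
    BackboneSpec,
    ConfigurationError,
    build_backbone,
    forward_with_grads,
    patch_transform_swin,
    patch_transform_vit,
)
from camfuse.backbones import (
    inverse_patch_transform_swin,
    inverse_patch_transform_vit,
)


def finite_difference_grads(model, acts, target_class, eps=1e-4):
    """Independent oracle: central differences of the head output with
    respect to each target-layer activation cell."""
    g = np.zeros_like(acts)
    it = np.nditer(acts, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        hi = acts.copy(); hi[idx] += eps
        lo = acts.copy(); lo[idx] -= eps
        g[idx] = (model.head(hi)[target_class] - model.head(lo)[target_class]) / (2 * eps)
    return g


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(family="vit", input_size=(60, 60), patch_size=16),  # not divisible
            dict(family="vit", input_size=(32, 64), patch_size=8),  # N=32 not square
            dict(family="swin", input_size=(48, 48), window_down=32),  # 48 % 32 != 0
            dict(family="swin", input_size=(96, 96), window_down=24),  # not power of 2
            dict(family="bogus"),
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            BackboneSpec(**kwargs)

    def test_yaml_json_round_trip(self, tmp_path, tiny_specs):
        for spec, suffix in zip(tiny_specs, (".yaml", ".json", ".yaml")):
            p = tmp_path / f"spec{suffix}"
            spec.save(p)
            assert BackboneSpec.load(p) == spec


class TestTargetLayerShapes:
    @pytest.mark.parametrize(
        "family,kwargs,expected",
        [
            # cnn: input / 2^depth, widths double per stage
            ("cnn", dict(input_size=(64, 64), embed_dim=8, depth=2), (16, 16, 16)),
            ("cnn", dict(input_size=(32, 32), embed_dim=4, depth=3), (16, 4, 4)),
            # vit: sqrt(N) x sqrt(N) with embed_dim channels
            ("vit", dict(input_size=(64, 64), patch_size=8, embed_dim=8), (8, 8, 8)),
            ("vit", dict(input_size=(32, 32), patch_size=4, embed_dim=8), (8, 8, 8)),
            # swin: (H/down, W/down) with embed_dim * (down/4) channels
            ("swin", dict(input_size=(64, 64), window_down=32, embed_dim=4), (32, 2, 2)),
            ("swin", dict(input_size=(32, 32), window_down=8, embed_dim=4), (8, 4, 4)),
        ],
    )
    def test_shape_law(self, family, kwargs, expected):
        spec = BackboneSpec(family, num_classes=2, seed=0, **kwargs)
        model = build_backbone(spec)
        img = np.random.default_rng(0).uniform(size=(3, *spec.input_size))
        assert model.features(img).shape == expected

    def test_same_seed_identical_weights(self):
        spec = BackboneSpec("cnn", input_size=(32, 32), embed_dim=4, depth=1, seed=9)
        a, b = build_backbone(spec), build_backbone(spec)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_weight_archive_round_trip(self, tmp_path, tiny_specs):
        spec = tiny_specs[0]
        a = build_backbone(spec)
        path = tmp_path / "w.npz"
        a.save_weights(path)
        b = build_backbone(
            BackboneSpec(**{**spec.to_dict(), "input_size": spec.input_size, "seed": 99})
        )
        b.load_weights(path)
        img = np.random.default_rng(1).uniform(size=(3, *spec.input_size))
        np.testing.assert_array_equal(a.features(img), b.features(img))


class TestPatchTransform:
    @pytest.mark.parametrize("n_tokens,dim,side", [(197, 16, 14), (5, 8, 2), (17, 4, 4)])
    def test_vit_shape_and_round_trip(self, rng, n_tokens, dim, side):
        tokens = rng.normal(size=(n_tokens, dim))
        spatial = patch_transform_vit(tokens)
        assert spatial.shape == (dim, side, side)
        # bit-exact inverse on the patch tokens (class token dropped)
        np.testing.assert_array_equal(inverse_patch_transform_vit(spatial), tokens[1:])

    def test_vit_row_major_layout(self):
        tokens = np.concatenate([[[99.0]], np.arange(4.0)[:, None]])
        spatial = patch_transform_vit(tokens)
        np.testing.assert_array_equal(spatial[0], [[0, 1], [2, 3]])

    @pytest.mark.parametrize("bad", [11, 3])
    def test_vit_non_square_rejected(self, rng, bad):
        with pytest.raises(ValueError):
            patch_transform_vit(rng.normal(size=(bad, 8)))

    def test_vit_too_few_tokens(self):
        with pytest.raises(ValueError):
            patch_transform_vit(np.ones((1, 8)))

    @pytest.mark.parametrize("grid,dim", [((7, 7), 96), ((2, 2), 8), ((2, 4), 5)])
    def test_swin_shape_and_round_trip(self, rng, grid, dim):
        tokens = rng.normal(size=(grid[0] * grid[1], dim))
        spatial = patch_transform_swin(tokens, grid)
        assert spatial.shape == (dim, *grid)
        np.testing.assert_array_equal(inverse_patch_transform_swin(spatial), tokens)

    def test_swin_inconsistent_count_rejected(self, rng):
        with pytest.raises(ValueError):
            patch_transform_swin(rng.normal(size=(50, 8)), (7, 7))


class TestForwardWithGrads:
    def test_gradient_of_mean_is_uniform(self, tiny_specs):
        # the head is GAP + linear, so d(logit)/dA is W[c]/(u*v) everywhere:
        # for a single activation map with unit head weight, exactly 1/(u*v)
        model = build_backbone(tiny_specs[0])
        img = np.random.default_rng(3).uniform(size=(3, 32, 32))
        out = forward_with_grads(model, img, target_class=1)
        _, u, v = out.activations.shape
        w = model.params["head.w"][1]
        np.testing.assert_allclose(
            out.gradients, np.broadcast_to(w[:, None, None] / (u * v), out.gradients.shape)
        )

    @pytest.mark.parametrize("family_idx", [0, 1, 2])
    def test_gradients_match_finite_differences(self, tiny_specs, family_idx):
        spec = tiny_specs[family_idx]
        model = build_backbone(spec)
        img = np.random.default_rng(family_idx).uniform(size=(3, *spec.input_size))
        out = forward_with_grads(model, img, "argmax")
        fd = finite_difference_grads(model, out.activations, out.target_class)
        sel = np.abs(out.gradients) > 1e-6
        rel = np.abs(fd[sel] - out.gradients[sel]) / np.abs(out.gradients[sel])
        assert rel.max() < 1e-3

    def test_argmax_equals_explicit_index(self, tiny_specs):
        model = build_backbone(tiny_specs[1])
        img = np.random.default_rng(4).uniform(size=(3, 32, 32))
        auto = forward_with_grads(model, img, "argmax")
        explicit = forward_with_grads(model, img, int(np.argmax(auto.class_scores)))
        np.testing.assert_array_equal(auto.gradients, explicit.gradients)
        assert auto.target_class == explicit.target_class

    def test_class_index_out_of_range(self, tiny_specs):
        model = build_backbone(tiny_specs[0])
        img = np.zeros((3, 32, 32))
        with pytest.raises(ValueError):
            forward_with_grads(model, img, 17)

    def test_wrong_image_shape_rejected(self, tiny_specs):
        model = build_backbone(tiny_specs[0])
        with pytest.raises(ValueError):
            model.features(np.zeros((3, 16, 16)))
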