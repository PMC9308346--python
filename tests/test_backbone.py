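"""Backbone architecture: convolution arithmetic, residual blocks, stage plan."""

import numpy as np
import pytest

from cytodet import nn
from cytodet.backbone import (
    DILATED,
    GROUPED,
    BackboneConfig,
    ConfigurationError,
    ConvLayerSpec,
    DCResNet,
    StageSpec,
    conv_output_size,
    conv_param_count,
    count_conv_layers,
    default_config,
    residual_dilated_block,
    residual_group_block,
)
from cytodet.nn.layers import GeometryError


def sliding_window_count(x, k, s=1, p=0, d=1):
    """Independent oracle: count valid kernel placements on a padded axis."""
    padded = x + 2 * p
    extent = (k - 1) * d + 1
    return len(range(0, padded - extent + 1, s))


def miniature_config(dilated=True):
    stages = [
        StageSpec(GROUPED, 1, (8, 8, 16), groups=4, stride=1),
        StageSpec(GROUPED, 1, (16, 16, 32), groups=4, stride=2),
        StageSpec(GROUPED, 1, (32, 32, 64), groups=4, stride=2),
    ]
    if dilated:
        stages.append(StageSpec(DILATED, 3, (64, 16, 64), dilation=2))
    return BackboneConfig(stem_channels=8, stages=tuple(stages),
                          head_dims=(32, 16, 2), input_size=64)


class TestConvOutputSize:
    @pytest.mark.parametrize("x,kwargs,expected", [
        # a dilation-2, padding-2 3x3 leaves the size unchanged
        (7, dict(kernel=3, dilation=2, padding=2, stride=1), 7),
        (14, dict(kernel=3, dilation=2, padding=2, stride=1), 14),
        (13, dict(kernel=1), 13),  # identity convolution
        (224, dict(kernel=7, dilation=1, padding=3, stride=2), 112),
    ])
    def test_examples(self, x, kwargs, expected):
        assert conv_output_size(x, ConvLayerSpec(**kwargs)) == expected

    @pytest.mark.parametrize("x", [5, 8, 17, 224])
    @pytest.mark.parametrize("kwargs", [
        dict(kernel=3, stride=1, padding=1),
        dict(kernel=3, stride=2, padding=1),
        dict(kernel=7, stride=2, padding=3),
        dict(kernel=3, stride=1, padding=2, dilation=2),
        dict(kernel=3, stride=2, padding=0),
    ])
    def test_matches_explicit_sliding_window(self, x, kwargs):
        spec = ConvLayerSpec(**kwargs)
        assert conv_output_size(x, spec) == sliding_window_count(
            x, spec.kernel, spec.stride, spec.padding, spec.dilation)

    def test_invalid_geometry_raises(self):
        with pytest.raises(GeometryError):
            conv_output_size(2, ConvLayerSpec(kernel=7))

    def test_indivisible_groups_rejected(self):
        with pytest.raises(ConfigurationError):
            ConvLayerSpec(kernel=3, groups=3, in_channels=4, out_channels=4)


class TestBlocks:
    def test_group_block_shape(self):
        block = residual_group_block(64, 128, 256, groups=32, dtype=np.float32)
        x = np.random.default_rng(0).random((1, 64, 56, 56), dtype=np.float32)
        block.eval()
        assert block.forward(x).shape == (1, 256, 56, 56)

    def test_group_block_stride_halves(self):
        block = residual_group_block(16, 16, 32, groups=4, stride=2)
        x = np.random.default_rng(0).random((1, 16, 8, 8), dtype=np.float32)
        block.eval()
        assert block.forward(x).shape == (1, 32, 4, 4)

    def test_grouped_parameter_reduction_is_exactly_1_over_g(self):
        dense = ConvLayerSpec(kernel=3, groups=1, in_channels=128,
                              out_channels=128)
        grouped = ConvLayerSpec(kernel=3, groups=32, in_channels=128,
                                out_channels=128)
        assert conv_param_count(dense) == 32 * conv_param_count(grouped)
        # realized layers agree with the closed form
        a = nn.Conv2d(128, 128, 3, groups=1, bias=False)
        b = nn.Conv2d(128, 128, 3, groups=32, bias=False)
        assert a.weight.size == conv_param_count(dense)
        assert b.weight.size == conv_param_count(grouped)

    def test_zeroed_residual_path_reproduces_shortcut(self):
        block = residual_dilated_block("A", 32, (32, 8, 32))
        block.eval()
        final_bn = block.main.layers[-1]
        final_bn.gamma.data[...] = 0.0
        final_bn.beta.data[...] = 0.0
        x = np.abs(np.random.default_rng(1).random((2, 32, 6, 6),
                                                   dtype=np.float32))
        np.testing.assert_allclose(block.forward(x), x, atol=1e-6)

    @pytest.mark.parametrize("variant", ["A", "B"])
    def test_dilated_block_preserves_spatial_size(self, variant):
        block = residual_dilated_block(variant, 1024, (1024, 256, 1024))
        block.eval()
        x = np.random.default_rng(2).random((1, 1024, 14, 14),
                                            dtype=np.float32) * 0.1
        assert block.forward(x).shape == (1, 1024, 14, 14)

    def test_variant_b_has_residual_conv_variant_a_not(self):
        a = residual_dilated_block("A", 64, (64, 16, 64))
        b = residual_dilated_block("B", 64, (64, 16, 64))
        assert a.shortcut is None and b.shortcut is not None

    def test_dilated_receptive_field_is_five_pixels(self):
        """Gradient-support probe: one output unit of a 3x3 d=2 conv sees a
        5x5 input patch."""
        conv = nn.Conv2d(1, 1, 3, padding=2, dilation=2, bias=False,
                         dtype=np.float64)
        conv.weight.data[...] = 1.0
        x = np.zeros((1, 1, 15, 15))
        y = conv.forward(x)
        dy = np.zeros_like(y)
        dy[0, 0, 7, 7] = 1.0
        dx = conv.backward(dy)
        rows = np.where(dx[0, 0].any(axis=1))[0]
        cols = np.where(dx[0, 0].any(axis=0))[0]
        assert rows.max() - rows.min() + 1 == 5
        assert cols.max() - cols.min() + 1 == 5

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ConfigurationError):
            residual_group_block(64, 100, 256, groups=32)


class TestBackbone:
    def test_default_build_structure(self):
        net = DCResNet(default_config())
        assert len(net.stages) == 5
        assert len(net.fc) == 3
        mults = [len(blocks) for blocks in net.stages]
        assert mults == [3, 4, 6, 3, 3]

    def test_default_layer_count_is_59(self):
        assert count_conv_layers(DCResNet(default_config())) == 59

    def test_count_conventions_on_reduced_plans(self):
        stem_only = DCResNet(BackboneConfig(stem_channels=8, stages=(),
                                            head_dims=(8, 8, 2)))
        assert count_conv_layers(stem_only, head_as_single_layer=False) == 1
        mini = DCResNet(miniature_config(dilated=False))
        # 1 stem + 3 blocks x 3 convs + head-as-one
        assert count_conv_layers(mini) == 11
        # all three grouped stages change channels => three projections
        assert count_conv_layers(mini, include_projections=True) == 14

    def test_miniature_forward_shapes_and_strides(self):
        net = DCResNet(miniature_config(), seed=1).eval()
        x = np.random.default_rng(0).random((2, 3, 64, 64), dtype=np.float32)
        feats = net.forward_features(x)
        assert feats.levels == [1, 2, 3, 4]
        assert [feats.strides[i] for i in feats.levels] == [4, 8, 16, 16]
        assert feats.spatial(3) == feats.spatial(4) == (4, 4)

    def test_shape_oracle_every_layer(self):
        """Each realized conv output size equals the arithmetic prediction."""
        net = DCResNet(miniature_config(), seed=1).eval()
        x = np.random.default_rng(0).random((1, 3, 64, 64), dtype=np.float32)
        net.forward_features(x)
        checked = 0
        for _, conv in net.all_conv_layers():
            v, x_shape, _, Ho, Wo = conv._cache
            spec = ConvLayerSpec(conv.kernel_size, conv.stride, conv.padding,
                                 conv.dilation, conv.groups,
                                 conv.in_channels, conv.out_channels)
            assert Ho == conv_output_size(x_shape[2], spec)
            assert Wo == conv_output_size(x_shape[3], spec)
            checked += 1
        assert checked == count_conv_layers(
            net, include_projections=True, head_as_single_layer=False)

    def test_batch_determinism_and_per_image_independence(self):
        net = DCResNet(miniature_config(), seed=2).eval()
        img = np.random.default_rng(3).random((1, 3, 64, 64), dtype=np.float32)
        pair = np.concatenate([img, img])
        feats = net.forward_features(pair)
        for level in feats.levels:
            np.testing.assert_array_equal(feats.maps[level][0],
                                          feats.maps[level][1])

    def test_classify_eval_deterministic_finite_normalized(self):
        net = DCResNet(miniature_config(), seed=4).eval()
        x = np.random.default_rng(5).random((3, 3, 64, 64), dtype=np.float32)
        s1 = net.forward_classify(x)
        s2 = net.forward_classify(x)
        np.testing.assert_array_equal(s1, s2)
        assert np.all(np.isfinite(s1))
        probs = nn.softmax(s1, axis=1)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_classify_rejects_wrong_input_size(self):
        net = DCResNet(miniature_config(), seed=4).eval()
        with pytest.raises(GeometryError):
            net.forward_classify(np.zeros((1, 3, 32, 32), dtype=np.float32))

    def test_too_small_input_raises(self):
        net = DCResNet(miniature_config(), seed=4).eval()
        with pytest.raises(GeometryError):
            net.forward_features(np.zeros((1, 3, 2, 2), dtype=np.float32))

    def test_dilated_stage_stride_two_rejected(self):
        with pytest.raises(ConfigurationError):
            StageSpec(DILATED, 3, (64, 16, 64), dilation=2, stride=2)

    def test_checkpoint_roundtrip(self):
        net = DCResNet(miniature_config(), seed=6).eval()
        x = np.random.default_rng(7).random((1, 3, 64, 64), dtype=np.float32)
        ref = net.forward_classify(x)
        arrays = [a.copy() for a in net.state_arrays()]
        other = DCResNet(miniature_config(), seed=99).eval()
        assert not np.allclose(other.forward_classify(x), ref)
        other.load_state_arrays(arrays)
        np.testing.assert_array_equal(other.forward_classify(x), ref)
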