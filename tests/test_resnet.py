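"""Architecture contracts: activations, specs, shapes, materialization."""

import numpy as np
import pytest

from gasfnet import _nn
from gasfnet.resnet import (
    ActivationParams,
    BlockSpec,
    build_baseline_resnet50,
    build_improved_resnet,
    count_parameters,
    describe,
    forward_shapes,
    materialize,
    relu,
    selu,
    _Bottleneck,
)

ALPHA, LAM = 1.6733, 1.0507


class TestActivations:
    @pytest.mark.parametrize("x,expected", [(3, 3), (-2, 0), (0, 0)])
    def test_relu_scalar(self, x, expected):
        assert relu(x) == expected

    def test_selu_at_one_equals_lambda(self):
        assert selu(1.0) == pytest.approx(LAM, abs=1e-12)

    def test_selu_continuous_at_zero(self):
        assert selu(0.0) == 0.0
        assert selu(-1e-12) == pytest.approx(0.0, abs=1e-11)

    def test_selu_negative_asymptote(self):
        assert selu(-20.0) == pytest.approx(-LAM * ALPHA, abs=1e-4)

    def test_selu_matches_scalar_loop_oracle(self, rng):
        x = rng.normal(size=1000) * 3
        import math

        expected = np.array(
            [LAM * v if v >= 0 else LAM * (ALPHA * math.exp(v) - ALPHA) for v in x]
        )
        np.testing.assert_allclose(selu(x), expected, atol=1e-12)

    def test_selu_layer_matches_function(self, rng):
        x = rng.normal(size=(64,))
        np.testing.assert_allclose(_nn.SELU().forward(x), selu(x), atol=1e-12)

    def test_selu_self_normalizes_standard_input(self):
        # for standard-normal input the SELU output stays near zero mean
        # and unit variance (the self-normalizing fixed point)
        x = np.random.default_rng(7).standard_normal(100_000)
        y = selu(x)
        assert abs(y.mean()) < 0.1
        assert abs(y.var() - 1.0) < 0.15

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ActivationParams("GELU")


class TestSpecs:
    def test_baseline_stage_plan(self):
        spec = build_baseline_resnet50()
        assert spec.block_counts == (3, 4, 6, 3)
        assert len(spec.auxiliary_shortcuts) == 0
        assert spec.n_classes == 7
        assert spec.activation.kind == "ReLU"
        for stage in spec.stages:
            for b in stage.blocks:
                assert not b.preactivation
                assert b.downsample_on == "conv1x1"

    def test_improved_has_five_shortcut_groups(self):
        spec = build_improved_resnet()
        aux = spec.auxiliary_shortcuts
        assert len(aux) == 5
        assert tuple(s.stride for s in aux) == (1, 2, 2, 2, 8)
        assert all(s.kernel == 1 for s in aux)
        assert spec.activation.kind == "SELU"

    def test_improved_downsampling_layout(self):
        spec = build_improved_resnet()
        first_blocks = [stage.blocks[0] for stage in spec.stages]
        # no average pooling in the first stage's bypass (no spatial change)
        assert first_blocks[0].bypass == "conv1x1"
        assert [b.bypass for b in first_blocks[1:]] == ["avgpool2x2+conv1x1"] * 3
        # stride 2 sits on the 3x3 conv; the 1x1 convs keep stride 1
        for b in first_blocks[1:]:
            assert b.trunk_strides == (1, 2, 1)
            assert b.preactivation
        # non-first blocks are identity-bypass
        for stage in spec.stages:
            for b in stage.blocks[1:]:
                assert b.bypass == "identity"

    def test_global_shortcut_maps_stem_to_final_channels(self):
        spec = build_improved_resnet()
        sc = spec.global_shortcut
        assert (sc.in_ch, sc.out_ch, sc.stride) == (64, 2048, 8)

    def test_identity_bypass_requires_matching_shape(self):
        with pytest.raises(ValueError):
            BlockSpec(in_ch=64, mid_ch=16, out_ch=128, bypass="identity")


class TestParameterCounts:
    def test_baseline_matches_independent_enumeration(self):
        # independent oracle: explicit per-layer enumeration of canonical
        # ResNet-50 (3-channel input, 1000 classes)
        widths = [(64, 64, 256), (256, 128, 512), (512, 256, 1024), (1024, 512, 2048)]
        blocks = (3, 4, 6, 3)
        total = 3 * 64 * 7 * 7 + 2 * 64  # stem conv + BN
        for (in_ch, mid, out), n in zip(widths, blocks):
            for b in range(n):
                cin = in_ch if b == 0 else out
                total += cin * mid + 2 * mid          # 1x1 conv + BN
                total += mid * mid * 9 + 2 * mid      # 3x3 conv + BN
                total += mid * out + 2 * out          # 1x1 conv + BN
                if b == 0:
                    total += cin * out + 2 * out      # projection bypass + BN
        total += 2048 * 1000 + 1000                   # fc
        assert total == 25_557_032  # published canonical ResNet-50 size
        spec = build_baseline_resnet50(n_classes=1000, in_channels=3)
        assert count_parameters(spec) == total

    def test_improved_has_strictly_more_parameters(self):
        base = build_baseline_resnet50()
        imp = build_improved_resnet()
        assert count_parameters(imp) > count_parameters(base)

    def test_materialized_count_matches_spec_count(self):
        spec = build_improved_resnet(n_classes=3, blocks=(1, 1, 1, 1), width=0.125)
        model = materialize(spec, seed=0)
        assert model.num_params == count_parameters(spec)


class TestForwardShapes:
    def test_canonical_224_trace(self):
        spec = build_improved_resnet()
        trace = {name: (side, ch) for name, side, ch in forward_shapes(spec, (1, 224, 224))}
        assert trace["stem"] == (56, 64)
        assert trace["Conv2_x"] == (56, 256)
        assert trace["Conv3_x"] == (28, 512)
        assert trace["Conv4_x"] == (14, 1024)
        assert trace["Conv5_x"] == (7, 2048)
        assert trace["logits"] == (0, 7)

    def test_global_shortcut_side_ratio_is_eight(self):
        spec = build_improved_resnet()
        trace = forward_shapes(spec, (1, 224, 224))
        stem_side = dict((n, s) for n, s, _ in trace)["stem"]
        final_side = dict((n, s) for n, s, _ in trace)["Conv5_x"]
        assert stem_side // final_side == spec.global_shortcut.stride == 8

    def test_rejects_side_not_divisible_by_32(self):
        with pytest.raises(ValueError, match="32"):
            forward_shapes(build_baseline_resnet50(), (1, 100, 100))

    def test_rejects_channel_mismatch(self):
        spec = build_improved_resnet()
        bad = spec.stages[1].blocks[0].__class__(
            in_ch=999, mid_ch=128, out_ch=512, stride=2,
            preactivation=True, bypass="avgpool2x2+conv1x1", downsample_on="conv3x3",
        )
        stages = list(spec.stages)
        stages[1] = stages[1].__class__(stages[1].name, (bad,) + stages[1].blocks[1:], stages[1].shortcut)
        broken = spec.__class__(
            name=spec.name, stages=tuple(stages), activation=spec.activation,
            global_shortcut=spec.global_shortcut, final_bn_act=True,
        )
        with pytest.raises(ValueError, match="Conv3_x"):
            forward_shapes(broken, (1, 64, 64))

    def test_describe_mentions_shortcuts(self):
        text = describe(build_improved_resnet(), input_side=224)
        assert "shortcut groups: 5" in text
        assert "stride 8" in text


class TestMaterialize:
    def test_same_seed_identical_parameters(self):
        spec = build_improved_resnet(n_classes=3, blocks=(1, 1, 1, 1), width=0.125)
        assert materialize(spec, seed=4).checksum() == materialize(spec, seed=4).checksum()

    def test_different_seed_different_parameters(self):
        spec = build_improved_resnet(n_classes=3, blocks=(1, 1, 1, 1), width=0.125)
        assert materialize(spec, seed=4).checksum() != materialize(spec, seed=5).checksum()

    def test_forward_emits_logits(self, rng):
        spec = build_improved_resnet(n_classes=5, blocks=(1, 1, 1, 1), width=0.125)
        model = materialize(spec, seed=0).train_mode(False)
        logits = model.forward(rng.normal(size=(2, 1, 32, 32)).astype(np.float32))
        assert logits.shape == (2, 5)

    def test_zeroed_trunk_identity_block(self, rng):
        # H(x) = F(x) + x: with every trunk parameter zeroed, an
        # identity-bypass pre-activation block is the identity map
        bs = BlockSpec(
            in_ch=8, mid_ch=4, out_ch=8, stride=1, preactivation=True,
            bypass="identity", downsample_on="conv3x3",
        )
        blk = _Bottleneck(bs, ActivationParams("SELU"), np.random.default_rng(0), 1.0, np.float64)
        for layer in blk.layers():
            for key in layer.params:
                layer.params[key][...] = 0.0
            layer.training = False
        x = rng.normal(size=(2, 8, 6, 6))
        np.testing.assert_allclose(blk.forward(x), x, atol=1e-12)

    def test_save_load_round_trip(self, tmp_path, rng):
        spec = build_improved_resnet(n_classes=3, blocks=(1, 1, 1, 1), width=0.125)
        model = materialize(spec, seed=0)
        x = rng.normal(size=(2, 1, 32, 32)).astype(np.float32)
        before = model.train_mode(False).forward(x)
        model.save(tmp_path / "m.npz")
        other = materialize(spec, seed=9)
        other.load(tmp_path / "m.npz")
        np.testing.assert_allclose(other.train_mode(False).forward(x), before, atol=1e-6)
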