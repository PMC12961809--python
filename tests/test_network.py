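"""Architecture contracts: shapes, attention coefficient ranges, gating
closed forms and gradient flow under deep supervision."""

import numpy as np
import pytest

from posam_ultra import LossWeights, NetworkConfig, PoSamUltraNet
from posam_ultra.autograd import Tensor
from posam_ultra.losses import composite_loss, total_loss
from posam_ultra.network import (
    CBAM,
    AttentionGate,
    ChannelAttention,
    ConvBlock,
    DecoderStage,
    SpatialAttention,
    Stem,
)
from posam_ultra.optim import Adam


def _rng():
    return np.random.default_rng(0)


class TestBuildingBlocks:
    def test_stem_shape_contract(self):
        stem = Stem(64, _rng())
        out = stem(np.zeros((1, 4, 256, 256)))
        assert out.shape == (1, 64, 64, 64)

    def test_stem_output_nonnegative(self):
        stem = Stem(8, _rng())
        out = stem(_rng().normal(size=(2, 4, 32, 32)))
        assert np.all(out.data >= 0)

    def test_stem_zero_weights_zero_output(self):
        stem = Stem(8, _rng())
        stem.conv.weight.data[:] = 0.0
        stem.bn.gamma.data[:] = 1.0
        stem.bn.beta.data[:] = 0.0
        out = stem(_rng().normal(size=(1, 4, 32, 32)))
        assert np.all(out.data == 0.0)

    def test_stem_rejects_wrong_channel_count(self):
        with pytest.raises(ValueError, match="4"):
            Stem(8, _rng())(np.zeros((1, 3, 32, 32)))

    @pytest.mark.parametrize("stride,expected", [(1, 32), (2, 16)])
    def test_conv_block_spatial_contract(self, stride, expected):
        block = ConvBlock(4, 8, _rng(), stride=stride)
        out = block(_rng().normal(size=(1, 4, 32, 32)))
        assert out.shape == (1, 8, expected, expected)
        assert np.all(out.data >= 0)


class TestAttention:
    def test_channel_weights_in_open_interval(self):
        ca = ChannelAttention(16, 4, _rng())
        m = ca(Tensor(_rng().normal(size=(2, 16, 8, 8))))
        assert m.shape == (2, 16, 1, 1)
        assert np.all((m.data > 0) & (m.data < 1))

    def test_identical_channels_get_identical_weights(self):
        # symmetry holds when the MLP treats the two channels identically
        ca = ChannelAttention(8, 4, _rng())
        ca.fc1.weight.data[:, 5] = ca.fc1.weight.data[:, 3]
        ca.fc2.weight.data[5] = ca.fc2.weight.data[3]
        ca.fc2.bias.data[5] = ca.fc2.bias.data[3]
        x = _rng().normal(size=(1, 8, 6, 6))
        x[0, 5] = x[0, 3]
        m = ca(Tensor(x))
        assert m.data[0, 3, 0, 0] == pytest.approx(m.data[0, 5, 0, 0], abs=1e-12)

    def test_channel_reduction_larger_than_width_rejected(self):
        with pytest.raises(ValueError):
            ChannelAttention(8, 16, _rng())

    def test_spatial_map_shape_and_range(self):
        sa = SpatialAttention(_rng())
        m = sa(Tensor(_rng().normal(size=(2, 8, 12, 12))))
        assert m.shape == (2, 1, 12, 12)
        assert np.all((m.data > 0) & (m.data < 1))

    def test_spatially_constant_input_gives_constant_interior_map(self):
        sa = SpatialAttention(_rng())
        m = sa(Tensor(np.full((1, 4, 16, 16), 0.7))).data[0, 0]
        interior = m[4:-4, 4:-4]
        assert np.ptp(interior) < 1e-12

    def test_cbam_attenuates_and_preserves_shape(self):
        cbam = CBAM(8, 4, _rng())
        x = Tensor(_rng().normal(size=(2, 8, 8, 8)))
        out, mc, ms = cbam(x, return_maps=True)
        assert out.shape == x.shape
        assert np.all(np.abs(out.data) <= np.abs(x.data) + 1e-15)
        # definitional composition
        manual = (x * mc).data * ms.data
        assert np.allclose(out.data, manual, atol=1e-12)

    def test_gate_zero_psi_gives_half_coefficients(self):
        gate = AttentionGate(8, 16, _rng())
        gate.psi.weight.data[:] = 0.0
        gate.psi.bias.data[:] = 0.0
        skip = Tensor(_rng().normal(size=(1, 8, 16, 16)))
        coarse = Tensor(_rng().normal(size=(1, 16, 8, 8)))
        out, alpha = gate(skip, coarse)
        assert np.all(alpha.data == 0.5)
        assert out.shape == skip.shape
        assert np.all(np.abs(out.data) <= np.abs(skip.data) + 1e-15)


class TestDecoderStage:
    def test_upsamples_by_two_and_orders_concat(self, monkeypatch):
        stage = DecoderStage(deep_ch=16, skip_ch=8, shallow_chs=[4], base_filters=4,
                             rng=_rng(), reduction=4)
        deep = Tensor(_rng().normal(size=(1, 16, 8, 8)))
        feats = [Tensor(_rng().normal(size=(1, 4, 32, 32))),
                 Tensor(_rng().normal(size=(1, 8, 16, 16)))]
        captured = []
        import posam_ultra.network as netmod
        original = netmod.concat

        def capture(parts, axis=1):
            captured.append([p.shape[1] for p in parts])
            return original(parts, axis=axis)

        monkeypatch.setattr(netmod, "concat", capture)
        out = stage(deep, feats)
        assert out.shape == (1, 8, 16, 16)          # 2x the deep resolution
        fusion_calls = [c for c in captured if len(c) == 3]
        assert fusion_calls == [[8, 8, 4]]           # up, gated skip, reduced C1

    def test_missing_encoder_stage_rejected(self):
        stage = DecoderStage(16, 8, [4], 4, _rng(), reduction=4)
        with pytest.raises(ValueError):
            stage(Tensor(np.zeros((1, 16, 8, 8))), [Tensor(np.zeros((1, 8, 16, 16)))])


class TestForward:
    @pytest.mark.parametrize("n_stages", [2, 3, 4])
    def test_output_resolution_matches_input(self, n_stages):
        cfg = NetworkConfig(base_filters=8, n_stages=n_stages, cbam_reduction=4,
                            dropout=0.0, seed=0)
        net = PoSamUltraNet(cfg)
        out = net.forward(np.random.default_rng(1).random((1, 4, 64, 64)))
        for head in (out.main, out.aux1, out.aux2):
            assert head.shape == (1, 1, 64, 64)
            assert np.all((head.data > 0) & (head.data < 1))

    def test_inference_main_equals_training_main_in_eval(self, tiny_cfg):
        net = PoSamUltraNet(tiny_cfg).eval()
        x = np.random.default_rng(2).random((1, 4, 64, 64))
        a = net.forward(x, mode="train").main.data
        b = net.forward(x, mode="infer").main.data
        assert np.array_equal(a, b)

    def test_wrong_channel_count_rejected(self, tiny_cfg):
        net = PoSamUltraNet(tiny_cfg)
        with pytest.raises(ValueError, match="4 input channels"):
            net.forward(np.zeros((1, 3, 64, 64)))

    def test_indivisible_size_error_names_required_multiple(self, tiny_cfg):
        net = PoSamUltraNet(tiny_cfg)
        with pytest.raises(ValueError, match="16"):
            net.forward(np.zeros((1, 4, 40, 40)))

    def test_construction_deterministic_per_seed(self, tiny_cfg):
        s1 = PoSamUltraNet(tiny_cfg).state_dict()
        s2 = PoSamUltraNet(tiny_cfg).state_dict()
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)


class TestGradientFlow:
    def test_every_parameter_updated_by_one_deep_supervised_step(self, tiny_cfg,
                                                                 phantom64):
        from posam_ultra.training import prepare_inputs

        img, msk = phantom64
        x, y = prepare_inputs([img], [msk])
        net = PoSamUltraNet(tiny_cfg)
        opt = Adam(net.parameters(), 1e-3)
        out = net.forward(x)
        lw = LossWeights()
        loss = total_loss(composite_loss(out.main, y[:, None], lw),
                          composite_loss(out.aux1, y[:, None], lw),
                          composite_loss(out.aux2, y[:, None], lw),
                          lw.lambda1, lw.lambda2)
        opt.zero_grad()
        loss.backward()
        for name, p in net.named_parameters():
            assert p.grad is not None and np.any(p.grad != 0.0), name
        before = {n: p.data.copy() for n, p in net.named_parameters()}
        opt.step()
        assert all(not np.array_equal(before[n], p.data)
                   for n, p in net.named_parameters())
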