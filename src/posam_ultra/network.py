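"""Attention-gated four-channel encoder-decoder for binary segmentation.

Layout (base filter count ``B``, ``n`` encoder stages, input ``H = W``):

* stem: 7x7 conv (stride 2) + BN + ReLU + 2x2 max-pool -> ``B`` channels at H/4
* encoder: ``n`` DownBlocks (two 3x3 conv+BN+ReLU blocks, CBAM, channel
  dropout); stage ``l`` carries ``B * 2^(l-1)`` channels, the first at H/4 and
  each later stage halving resolution via a stride-2 first conv
* decoder: ``n - 1`` stages; each upsamples bilinearly (then 3x3 conv),
  attention-gates the matching encoder skip with the coarser feature as the
  gating signal, average-pools every shallower encoder map to the stage
  resolution (1x1-conv-reduced to ``B`` channels), concatenates everything,
  fuses with a 3x3 conv and refines with CBAM ("extended" skip connections)
* head: two plain upsample+conv stages back to full resolution, then a 1x1
  conv + sigmoid
* deep supervision: auxiliary sigmoid heads on the decoder features at 1/4
  and 1/2 resolution, bilinearly upsampled to the input size

All attention coefficients (channel, spatial, gates) are sigmoid outputs and
therefore lie strictly in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import (
    Tensor,
    as_tensor,
    avgpool2d,
    channel_max,
    channel_mean,
    concat,
    dropout2d,
    global_avg_pool,
    global_max_pool,
    maxpool2d,
    upsample_bilinear,
)
from .nn import BatchNorm2d, Conv2d, Module
from .types import NetworkConfig

__all__ = [
    "ConvBlock",
    "Stem",
    "DownBlock",
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "AttentionGate",
    "DecoderStage",
    "PoSamUltraNet",
    "SegmentationOutput",
]


@dataclass
class SegmentationOutput:
    """Main probability map plus the two auxiliary deep-supervision maps
    (``None`` in inference mode)."""

    main: Tensor
    aux1: Tensor | None = None
    aux2: Tensor | None = None


class ConvBlock(Module):
    """3x3 conv (no bias; BN absorbs shifts) + batch norm + ReLU."""

    def __init__(self, in_ch: int, out_ch: int, rng, stride: int = 1):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, 3, rng, stride=stride, bias=False)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class Stem(Module):
    """7x7 stride-2 conv + BN + ReLU + 2x2 max-pool: 4 channels -> B at H/4."""

    def __init__(self, base_filters: int, rng):
        super().__init__()
        self.conv = Conv2d(4, base_filters, 7, rng, stride=2, bias=False)
        self.bn = BatchNorm2d(base_filters)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        if x.shape[1] != 4:
            raise ValueError(f"stem expects 4 input channels, got {x.shape[1]}")
        return maxpool2d(self.bn(self.conv(x)).relu(), 2)


class ChannelAttention(Module):
    """Squeeze-style channel gate: shared two-layer 1x1-conv MLP applied to
    global average- and max-pooled descriptors, summed, sigmoid."""

    def __init__(self, n_ch: int, reduction: int, rng):
        super().__init__()
        if n_ch < reduction:
            raise ValueError(
                f"channel attention needs C >= reduction (C={n_ch}, r={reduction})")
        hidden = max(1, n_ch // reduction)
        self.fc1 = Conv2d(n_ch, hidden, 1, rng)
        self.fc2 = Conv2d(hidden, n_ch, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = self.fc2(self.fc1(global_avg_pool(x)).relu())
        mx = self.fc2(self.fc1(global_max_pool(x)).relu())
        return (avg + mx).sigmoid()


class SpatialAttention(Module):
    """Spatial gate: channel mean/max descriptor -> 7x7 conv -> sigmoid."""

    def __init__(self, rng):
        super().__init__()
        self.conv = Conv2d(2, 1, 7, rng)

    def forward(self, x: Tensor) -> Tensor:
        desc = concat([channel_mean(x), channel_max(x)], axis=1)
        return self.conv(desc).sigmoid()


class CBAM(Module):
    """Sequential channel then spatial attention; shape preserving."""

    def __init__(self, n_ch: int, reduction: int, rng):
        super().__init__()
        self.channel = ChannelAttention(n_ch, reduction, rng)
        self.spatial = SpatialAttention(rng)

    def forward(self, x: Tensor, return_maps: bool = False):
        mc = self.channel(x)
        fc = x * mc
        ms = self.spatial(fc)
        out = fc * ms
        return (out, mc, ms) if return_maps else out


class AttentionGate(Module):
    """Additive attention gate on a skip connection.

    ``alpha = sigmoid(psi(ReLU(W_s * skip + W_g * up(gate))))`` with one
    coefficient per spatial location; output is ``alpha * skip``.
    """

    def __init__(self, skip_ch: int, gate_ch: int, rng, inter_ch: int | None = None):
        super().__init__()
        inter = inter_ch or max(1, skip_ch // 2)
        self.w_s = Conv2d(skip_ch, inter, 1, rng)
        self.w_g = Conv2d(gate_ch, inter, 1, rng)
        self.psi = Conv2d(inter, 1, 1, rng)

    def forward(self, skip: Tensor, gate: Tensor):
        gate_up = upsample_bilinear(gate, skip.shape[2:])
        alpha = self.psi((self.w_s(skip) + self.w_g(gate_up)).relu()).sigmoid()
        return skip * alpha, alpha


class DownBlock(Module):
    """Two conv blocks (first optionally stride 2) + CBAM + channel dropout."""

    def __init__(self, in_ch: int, out_ch: int, rng, downsample: bool = False,
                 reduction: int = 16, dropout: float = 0.0, dropout_rng=None):
        super().__init__()
        self.block1 = ConvBlock(in_ch, out_ch, rng, stride=2 if downsample else 1)
        self.block2 = ConvBlock(out_ch, out_ch, rng)
        self.cbam = CBAM(out_ch, reduction, rng)
        self.dropout = dropout
        self._dropout_rng = dropout_rng or np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cbam(self.block2(self.block1(x)))
        return dropout2d(y, self.dropout, self._dropout_rng, self.training)


class DecoderStage(Module):
    """One extended-skip decoder stage.

    Concatenation order: ``[up(F_deep), gated C_l, C_(l-1), ..., C_1]``, the
    shallower maps average-pooled to the stage resolution and reduced to
    ``base_filters`` channels by 1x1 convolutions.
    """

    def __init__(self, deep_ch: int, skip_ch: int, shallow_chs: list[int],
                 base_filters: int, rng, reduction: int = 16):
        super().__init__()
        self.up_conv = ConvBlock(deep_ch, skip_ch, rng)
        self.gate = AttentionGate(skip_ch, deep_ch, rng)
        self.reducers = [Conv2d(c, base_filters, 1, rng) for c in shallow_chs]
        fuse_in = skip_ch + skip_ch + base_filters * len(shallow_chs)
        self.fuse = ConvBlock(fuse_in, skip_ch, rng)
        self.cbam = CBAM(skip_ch, reduction, rng)

    def forward(self, deep: Tensor, encoder_feats: list[Tensor]) -> Tensor:
        if not encoder_feats:
            raise ValueError("decoder stage requires encoder features")
        *shallow, skip = encoder_feats
        if len(shallow) != len(self.reducers):
            raise ValueError(
                f"expected {len(self.reducers)} shallower encoder stages, "
                f"got {len(shallow)}")
        target = skip.shape[2:]
        up = self.up_conv(upsample_bilinear(deep, target))
        gated, _ = self.gate(skip, deep)
        parts = [up, gated]
        for feat, reducer in zip(reversed(shallow), reversed(self.reducers)):
            factor = feat.shape[2] // target[0]
            pooled = avgpool2d(feat, factor) if factor > 1 else feat
            parts.append(reducer(pooled))
        return self.cbam(self.fuse(concat(parts, axis=1)))


class PoSamUltraNet(Module):
    """The full segmentation network; see the module docstring for layout."""

    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        drop_rng = np.random.default_rng((cfg.seed + 1) % (2**31))
        b, n, r = cfg.base_filters, cfg.n_stages, cfg.cbam_reduction
        chs = [b * 2**i for i in range(n)]

        self.stem = Stem(b, rng)
        self.encoder = [
            DownBlock(chs[max(i - 1, 0)], chs[i], rng, downsample=i > 0,
                      reduction=r, dropout=cfg.dropout, dropout_rng=drop_rng)
            for i in range(n)
        ]
        self.decoder = [
            DecoderStage(chs[l + 1], chs[l], chs[:l], b, rng, reduction=r)
            for l in reversed(range(n - 1))
        ]
        self.up_half = ConvBlock(b, b, rng)
        self.up_full = ConvBlock(b, b, rng)
        self.head = Conv2d(b, 1, 1, rng)
        self.aux1_head = Conv2d(b, 1, 1, rng)
        self.aux2_head = Conv2d(b, 1, 1, rng)

    # -- helpers -----------------------------------------------------------
    def _validate(self, x: Tensor) -> Tensor:
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        if x.ndim != 4:
            raise ValueError("input must be (N, 4, H, W) or (4, H, W)")
        if x.shape[1] != 4:
            raise ValueError(f"expected 4 input channels, got {x.shape[1]}")
        n, c, h, w = x.shape
        factor = 2 ** (self.cfg.n_stages + 1)
        if h != w or h % factor:
            raise ValueError(
                f"spatial size must be square and divisible by {factor}, got {h}x{w}")
        return x

    def forward(self, x, mode: str = "train") -> SegmentationOutput:
        x = self._validate(as_tensor(x))
        h, w = x.shape[2:]

        feats = []
        f = self.stem(x)
        for block in self.encoder:
            f = block(f)
            feats.append(f)

        deep = feats[-1]
        for stage, l in zip(self.decoder, reversed(range(self.cfg.n_stages - 1))):
            deep = stage(deep, feats[: l + 1])

        quarter = deep                                        # B channels @ H/4
        half = self.up_half(upsample_bilinear(quarter, (h // 2, w // 2)))
        full = self.up_full(upsample_bilinear(half, (h, w)))
        main = self.head(full).sigmoid()

        if mode == "infer":
            return SegmentationOutput(main=main)
        aux1 = upsample_bilinear(self.aux1_head(quarter).sigmoid(), (h, w))
        aux2 = upsample_bilinear(self.aux2_head(half).sigmoid(), (h, w))
        return SegmentationOutput(main=main, aux1=aux1, aux2=aux2)

    def predict_proba(self, x) -> np.ndarray:
        """Inference-mode probabilities as a numpy array (N, 1, H, W)."""
        was_training = self.training
        self.eval()
        out = self.forward(x, mode="infer").main.data
        if was_training:
            self.train()
        return out
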