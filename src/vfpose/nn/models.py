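"""Network architectures for vocal-fold pose estimation.

Three variants share a MobileNetV2 encoder:

* ``heatmap`` — U-Net decoder regressing a 3-channel Gaussian heatmap
  stack at input resolution (sigmoid output).
* ``segmentation`` — same encoder/decoder with a 1-channel sigmoid output
  for the glottal-gap mask.
* ``direct`` — the encoder followed by two separable convolutions, global
  average pooling and a linear head emitting 6 sigmoid-activated values
  (normalized x, y for LV, RV, A).

The encoder is the standard MobileNetV2 layout: a stride-2 stem of 32
filters, 17 inverted residual blocks, and a final 1x1 projection that
brings the bottleneck to 576 channels (at width 1.0). Skip connections are
tapped at output strides 2, 4, 8 and 16; the bottleneck sits at stride 32.
A width multiplier scales every channel count so small variants can train
on CPU.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    F32,
    BatchNorm2d,
    Conv2d,
    DepthwiseConv2d,
    GlobalAvgPool,
    Layer,
    Linear,
    ReLU,
    Sequential,
    Sigmoid,
    Upsample2x,
)

# MobileNetV2 inverted-residual schedule: (expansion t, channels c, repeats n, stride s)
_IR_SCHEDULE = [
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
]
_BOTTLENECK_CH = 576
_DECODER_CH = (256, 128, 64, 32)


def scaled(ch: int, width: float) -> int:
    """Width-multiplied channel count, rounded to a multiple of 4, min 4."""
    return max(4, int(round(ch * width / 4)) * 4)


def conv_bn_relu(in_ch, out_ch, k, stride, rng) -> Sequential:
    return Sequential(
        Conv2d(in_ch, out_ch, k=k, stride=stride, rng=rng),
        BatchNorm2d(out_ch),
        ReLU(),
    )


class InvertedResidual(Layer):
    """1x1 expand -> 3x3 depthwise -> 1x1 project, residual when possible."""

    def __init__(self, in_ch, out_ch, stride, expand, rng):
        mid = in_ch * expand
        layers: list[Layer] = []
        if expand != 1:
            layers += [Conv2d(in_ch, mid, k=1, rng=rng), BatchNorm2d(mid), ReLU()]
        layers += [
            DepthwiseConv2d(mid, k=3, stride=stride, rng=rng),
            BatchNorm2d(mid),
            ReLU(),
            Conv2d(mid, out_ch, k=1, rng=rng),
            BatchNorm2d(out_ch),
        ]
        self.body = Sequential(*layers)
        self.use_res = stride == 1 and in_ch == out_ch

    def params(self):
        return self.body.params()

    def forward(self, x, train):
        out = self.body.forward(x, train)
        if self.use_res:
            out = out + x
        return out

    def backward(self, g):
        gx = self.body.backward(g)
        if self.use_res:
            gx = gx + g
        return gx


class MobileNetV2Encoder(Layer):
    """Encoder with skip taps. forward returns (bottleneck, skips);
    backward takes (g_bottleneck, g_skips)."""

    def __init__(self, width: float, rng: np.random.Generator):
        stem_ch = scaled(32, width)
        self.stages: list[Layer] = [conv_bn_relu(3, stem_ch, 3, 2, rng)]
        stage_strides = [2]  # cumulative output stride after each stage
        in_ch = stem_ch
        stride_now = 2
        self.stage_out_ch = [stem_ch]
        for t, c, n, s in _IR_SCHEDULE:
            out_ch = scaled(c, width)
            for i in range(n):
                st = s if i == 0 else 1
                self.stages.append(InvertedResidual(in_ch, out_ch, st, t, rng))
                stride_now *= st
                stage_strides.append(stride_now)
                self.stage_out_ch.append(out_ch)
                in_ch = out_ch
        bneck = scaled(_BOTTLENECK_CH, width)
        self.stages.append(conv_bn_relu(in_ch, bneck, 1, 1, rng))
        stage_strides.append(stride_now)
        self.stage_out_ch.append(bneck)
        self.out_ch = bneck

        # last stage index at each output stride 2, 4, 8, 16 = skip taps
        self.tap_idx: list[int] = []
        self.skip_ch: list[int] = []
        for target in (2, 4, 8, 16):
            idx = max(i for i, s in enumerate(stage_strides) if s == target)
            self.tap_idx.append(idx)
            self.skip_ch.append(self.stage_out_ch[idx])

    def params(self):
        return [p for s in self.stages for p in s.params()]

    def forward(self, x, train):
        skips = []
        for i, stage in enumerate(self.stages):
            x = stage.forward(x, train)
            if i in self.tap_idx:
                skips.append(x)
        return x, skips

    def backward(self, g, g_skips):
        by_idx = dict(zip(self.tap_idx, g_skips))
        for i in range(len(self.stages) - 1, -1, -1):
            if i in by_idx and i != len(self.stages) - 1:
                g = g + by_idx[i]
            g = self.stages[i].backward(g)
        return g


class _DecoderBlock(Layer):
    """Upsample x2, concatenate the stride-matched encoder skip, two
    3x3 conv+BN+ReLU."""

    def __init__(self, in_ch, skip_ch, out_ch, rng):
        self.up = Upsample2x()
        self.skip_ch = skip_ch
        self.convs = Sequential(
            Conv2d(in_ch + skip_ch, out_ch, k=3, rng=rng),
            BatchNorm2d(out_ch),
            ReLU(),
            Conv2d(out_ch, out_ch, k=3, rng=rng),
            BatchNorm2d(out_ch),
            ReLU(),
        )

    def params(self):
        return self.convs.params()

    def forward(self, x, skip, train):
        up = self.up.forward(x, train)
        cat = np.concatenate([up, skip], axis=1)
        self._split = up.shape[1]
        return self.convs.forward(cat, train)

    def backward(self, g):
        gcat = self.convs.backward(g)
        g_up, g_skip = gcat[:, : self._split], gcat[:, self._split :]
        return self.up.backward(np.ascontiguousarray(g_up)), np.ascontiguousarray(g_skip)


class _UNet(Layer):
    """Encoder + 4 decoder blocks + final upsample and 3-conv head."""

    def __init__(self, out_channels: int, width: float, rng: np.random.Generator):
        self.encoder = MobileNetV2Encoder(width, rng)
        dec_ch = [scaled(c, width) for c in _DECODER_CH]
        skips = self.encoder.skip_ch  # strides 2, 4, 8, 16
        in_ch = self.encoder.out_ch
        self.blocks: list[_DecoderBlock] = []
        for out_ch, skip_ch in zip(dec_ch, reversed(skips)):
            self.blocks.append(_DecoderBlock(in_ch, skip_ch, out_ch, rng))
            in_ch = out_ch
        head_ch = max(8, in_ch // 2)
        self.head = Sequential(
            Upsample2x(),  # stride 2 -> full resolution
            Conv2d(in_ch, head_ch, k=3, rng=rng),
            ReLU(),
            Conv2d(head_ch, head_ch, k=3, rng=rng),
            ReLU(),
            Conv2d(head_ch, out_channels, k=3, bias=True, rng=rng),
            Sigmoid(),
        )

    def params(self):
        return (
            self.encoder.params()
            + [p for b in self.blocks for p in b.params()]
            + self.head.params()
        )

    def forward(self, x, train):
        x, skips = self.encoder.forward(x, train)
        for block, skip in zip(self.blocks, reversed(skips)):
            x = block.forward(x, skip, train)
        return self.head.forward(x, train)

    def backward(self, g):
        g = self.head.backward(g)
        g_skips = []
        for block in reversed(self.blocks):
            g, g_skip = block.backward(g)
            g_skips.append(g_skip)
        # iterating blocks in reverse visits the shallowest skip first, so
        # g_skips is already in encoder tap order (stride 2, 4, 8, 16)
        return self.encoder.backward(g, g_skips)


class _DirectNet(Layer):
    """Encoder + two separable convolutions + GAP + linear 6-value head."""

    def __init__(self, width: float, rng: np.random.Generator):
        self.encoder = MobileNetV2Encoder(width, rng)
        ch = self.encoder.out_ch
        head_ch = scaled(128, width)
        self.neck = Sequential(
            # separable conv 1
            DepthwiseConv2d(ch, k=3, rng=rng),
            Conv2d(ch, head_ch, k=1, rng=rng),
            BatchNorm2d(head_ch),
            ReLU(),
            # separable conv 2
            DepthwiseConv2d(head_ch, k=3, rng=rng),
            Conv2d(head_ch, head_ch, k=1, rng=rng),
            BatchNorm2d(head_ch),
            ReLU(),
            GlobalAvgPool(),
            Linear(head_ch, 6, rng=rng),
            Sigmoid(),
        )

    def params(self):
        return self.encoder.params() + self.neck.params()

    def forward(self, x, train):
        x, skips = self.encoder.forward(x, train)
        self._skip_shapes = [s.shape for s in skips]
        return self.neck.forward(x, train)

    def backward(self, g):
        g = self.neck.backward(g)
        zero_skips = [np.zeros(s, dtype=F32) for s in self._skip_shapes]
        return self.encoder.backward(g, zero_skips)


def count_params(net: Layer) -> int:
    return int(sum(p.value.size for p in net.params()))
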