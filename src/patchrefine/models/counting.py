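"""Analytic parameter and FLOP accounting from layer shapes.

FLOPs are counted as multiply-accumulate operations (MACs) of one forward
pass: convolutions and dense layers only; normalization, pooling, activation
and interpolation are excluded.  Parameter counts include convolution/dense
weights and biases plus batch-norm affine parameters (the convention under
which a ResNet-50 totals 25.56M with its classifier and 23.5M without).

All architectures here are fully convolutional apart from fixed-cost
global-pooling branches, so MACs scale with input area (the x4 law under
input doubling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

__all__ = ["OpCount", "LayerCost", "count_ops", "ARCHITECTURES"]


class OpCount(NamedTuple):
    params: int
    flops: int  # multiply-accumulates


@dataclass
class LayerCost:
    name: str
    params: int
    flops: int


def _conv_out(n: int, k: int, stride: int, pad: int, dilation: int = 1) -> int:
    return (n + 2 * pad - dilation * (k - 1) - 1) // stride + 1


@dataclass
class _Tally:
    layers: list[LayerCost] = field(default_factory=list)

    def conv(self, name: str, cin: int, cout: int, k: int, out_h: int, out_w: int,
             bias: bool = False) -> None:
        params = cin * cout * k * k + (cout if bias else 0)
        flops = out_h * out_w * cout * cin * k * k
        self.layers.append(LayerCost(name, params, flops))

    def bn(self, name: str, c: int) -> None:
        self.layers.append(LayerCost(name, 2 * c, 0))

    def dense(self, name: str, cin: int, cout: int) -> None:
        self.layers.append(LayerCost(name, cin * cout + cout, cin * cout))

    def total(self) -> OpCount:
        return OpCount(sum(l.params for l in self.layers), sum(l.flops for l in self.layers))


# ---------------------------------------------------------------------------
# ResNet-50 encoder (classifier removed)
# ---------------------------------------------------------------------------

def _bottleneck(t: _Tally, name: str, cin: int, mid: int, cout: int,
                stride: int, h: int, w: int, downsample: bool) -> tuple[int, int]:
    t.conv(f"{name}.conv1", cin, mid, 1, h, w)
    t.bn(f"{name}.bn1", mid)
    h2, w2 = _conv_out(h, 3, stride, 1), _conv_out(w, 3, stride, 1)
    t.conv(f"{name}.conv2", mid, mid, 3, h2, w2)
    t.bn(f"{name}.bn2", mid)
    t.conv(f"{name}.conv3", mid, cout, 1, h2, w2)
    t.bn(f"{name}.bn3", cout)
    if downsample:
        t.conv(f"{name}.downsample", cin, cout, 1, h2, w2)
        t.bn(f"{name}.downsample_bn", cout)
    return h2, w2


def _resnet50_encoder(t: _Tally, h: int, w: int, dilated: bool = False):
    """Emit the encoder's layers; returns per-stage (channels, h, w) for skips."""
    h, w = _conv_out(h, 7, 2, 3), _conv_out(w, 7, 2, 3)
    t.conv("stem.conv", 3, 64, 7, h, w)
    t.bn("stem.bn", 64)
    stem = (64, h, w)
    h, w = _conv_out(h, 3, 2, 1), _conv_out(w, 3, 2, 1)  # maxpool, no MACs

    stages = []
    cin = 64
    cfg = [  # (mid, cout, blocks, stride)
        (64, 256, 3, 1),
        (128, 512, 4, 2),
        (256, 1024, 6, 2),
        (512, 2048, 3, 2),
    ]
    for s, (mid, cout, blocks, stride) in enumerate(cfg, start=1):
        if dilated and s >= 3:
            stride = 1  # dilation keeps resolution; params/MACs unchanged by rate
        for b in range(blocks):
            st = stride if b == 0 else 1
            h, w = _bottleneck(t, f"layer{s}.{b}", cin if b == 0 else cout,
                               mid, cout, st, h, w, downsample=(b == 0))
        cin = cout
        stages.append((cout, h, w))
    return stem, stages


# ---------------------------------------------------------------------------
# Architectures
# ---------------------------------------------------------------------------

def _arch_resnet50(t: _Tally, h: int, w: int) -> None:
    _resnet50_encoder(t, h, w)


def _fcn_aux(t: _Tally, c_l3: int, h3: int, w3: int) -> None:
    # auxiliary head on the layer-3 feature map (as in the torchvision models)
    t.conv("aux.conv", c_l3, 256, 3, h3, w3)
    t.bn("aux.bn", 256)
    t.conv("aux.cls", 256, 1, 1, h3, w3, bias=True)


def _arch_fcn(t: _Tally, h: int, w: int) -> None:
    _, stages = _resnet50_encoder(t, h, w, dilated=True)
    (c3, h3, w3), (c4, h4, w4) = stages[2], stages[3]
    t.conv("head.conv", c4, 512, 3, h4, w4)
    t.bn("head.bn", 512)
    t.conv("head.cls", 512, 1, 1, h4, w4, bias=True)
    _fcn_aux(t, c3, h3, w3)


def _arch_deeplabv3(t: _Tally, h: int, w: int) -> None:
    _, stages = _resnet50_encoder(t, h, w, dilated=True)
    (c3, h3, w3), (c4, h4, w4) = stages[2], stages[3]
    # ASPP: 1x1, three dilated 3x3 (rates 12/24/36), global-pool branch
    t.conv("aspp.b0", c4, 256, 1, h4, w4)
    t.bn("aspp.b0_bn", 256)
    for r in (12, 24, 36):
        t.conv(f"aspp.b{r}", c4, 256, 3, h4, w4)
        t.bn(f"aspp.b{r}_bn", 256)
    t.conv("aspp.pool", c4, 256, 1, 1, 1)  # on globally pooled features
    t.bn("aspp.pool_bn", 256)
    t.conv("aspp.project", 5 * 256, 256, 1, h4, w4)
    t.bn("aspp.project_bn", 256)
    t.conv("head.conv", 256, 256, 3, h4, w4)
    t.bn("head.bn", 256)
    t.conv("head.cls", 256, 1, 1, h4, w4, bias=True)
    _fcn_aux(t, c3, h3, w3)


def _arch_unet(t: _Tally, h: int, w: int) -> None:
    stem, stages = _resnet50_encoder(t, h, w)
    skips = [stages[2], stages[1], stages[0], stem]  # deepest skip first
    cin, hh, ww = stages[3]
    dec_channels = [512, 256, 128, 64]
    for d, ((cs, hs, ws), cd) in enumerate(zip(skips, dec_channels)):
        hh, ww = hs, ws  # upsample x2 to the skip's resolution (no MACs)
        t.conv(f"dec{d}.conv1", cin + cs, cd, 3, hh, ww, bias=True)
        t.conv(f"dec{d}.conv2", cd, cd, 3, hh, ww, bias=True)
        cin = cd
    hh, ww = hh * 2, ww * 2  # final upsample back to input resolution
    t.conv("dec4.conv1", cin, 32, 3, hh, ww, bias=True)
    t.conv("dec4.conv2", 32, 32, 3, hh, ww, bias=True)
    t.conv("head.cls", 32, 1, 1, hh, ww, bias=True)


def _arch_segnet(t: _Tally, h: int, w: int) -> None:
    _, stages = _resnet50_encoder(t, h, w)
    cin, hh, ww = stages[3]
    for d, cd in enumerate([1024, 512, 256, 128, 64]):
        hh, ww = hh * 2, ww * 2  # upsample x2
        t.conv(f"dec{d}.conv", cin, cd, 3, hh, ww)
        t.bn(f"dec{d}.bn", cd)
        cin = cd
    t.conv("head.cls", cin, 1, 1, hh, ww, bias=True)


def _arch_tiny(t: _Tally, h: int, w: int) -> None:
    t.conv("conv1", 3, 16, 3, h, w, bias=True)
    t.conv("conv2", 16, 32, 3, h // 2, w // 2, bias=True)
    t.conv("conv3", 32, 32, 3, h // 2, w // 2, bias=True)
    t.conv("conv4", 32, 16, 3, h, w, bias=True)
    t.conv("conv5", 16, 1, 1, h, w, bias=True)


ARCHITECTURES = {
    "tiny": _arch_tiny,
    "resnet50": _arch_resnet50,
    "fcn": _arch_fcn,
    "deeplabv3": _arch_deeplabv3,
    "unet": _arch_unet,
    "segnet": _arch_segnet,
}


def count_ops(architecture_id: str, input_size: tuple[int, int]) -> OpCount:
    """Analytic (params, MACs) of one forward pass at ``input_size``."""
    if architecture_id not in ARCHITECTURES:
        raise ValueError(
            f"unknown architecture {architecture_id!r}; choose from {sorted(ARCHITECTURES)}"
        )
    t = _Tally()
    ARCHITECTURES[architecture_id](t, int(input_size[0]), int(input_size[1]))
    return t.total()


def layer_costs(architecture_id: str, input_size: tuple[int, int]) -> list[LayerCost]:
    if architecture_id not in ARCHITECTURES:
        raise ValueError(
            f"unknown architecture {architecture_id!r}; choose from {sorted(ARCHITECTURES)}"
        )
    t = _Tally()
    ARCHITECTURES[architecture_id](t, int(input_size[0]), int(input_size[1]))
    return t.layers
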