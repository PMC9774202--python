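"""Backbone builders, analytic cost model, and the lightweighting rewriter.

Four desk-scale CNN families (``alexnet_s``, ``vgg_s``, ``googlenet_s``,
``resnet_s``) are expressed in the block IR of :mod:`fedprune.ir`.  They are
deliberately small (2–4 conv stages, well under 1M parameters at width 1.0):
the object of study is the federated pruning framework, not ImageNet-scale
capacity.

The lightweighting pass :func:`lighten` applies four rewrites:

1. every standard Dk×Dk conv (Dk>1) becomes a depthwise conv plus a 1×1
   pointwise conv — cost ratio ``1/N + 1/Dk²`` relative to the original;
2. residual blocks become inverted residuals (expand → depthwise → linear
   1×1 projection) with a linear bottleneck: no nonlinearity on the
   low-dimensional projection output;
3. a pointwise feature-generation conv sitting immediately before global
   average pooling is moved after it, so it runs at 1×1 spatial resolution;
4. a pointwise projection conv immediately preceding that feature conv is
   removed (the cheap post-pool feature layer no longer needs it).

Cost accounting uses multiply-accumulate operations (MACs) as the unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import List

from .ir import (
    Conv,
    Dense,
    GlobalAvgPool,
    Inception,
    InvertedResidual,
    ModelSpec,
    Pool,
    Residual,
    conv_out,
    infer_shapes,
)

__all__ = [
    "ConvSpec",
    "flops_standard",
    "flops_depthwise_separable",
    "cost_ratio",
    "BACKBONE_NAMES",
    "build_backbone",
    "lighten",
]

BACKBONE_NAMES = ("alexnet_s", "vgg_s", "googlenet_s", "resnet_s")


@dataclass(frozen=True)
class ConvSpec:
    """A single convolution for cost analysis.

    ``df`` is the (square) input feature-map size, ``dk`` the kernel size,
    ``m``/``n`` the input/output channel counts.
    """

    df: int
    dk: int
    m: int
    n: int
    stride: int = 1
    kind: str = "standard"

    def __post_init__(self) -> None:
        if min(self.df, self.dk, self.m, self.n, self.stride) < 1:
            raise ValueError("all ConvSpec fields must be positive integers")
        if self.kind == "depthwise" and self.n != self.m:
            raise ValueError("depthwise conv requires n == m")
        if self.kind == "pointwise" and self.dk != 1:
            raise ValueError("pointwise conv requires dk == 1")

    @property
    def df_out(self) -> int:
        return conv_out(self.df, self.dk, self.stride)


def flops_standard(c: ConvSpec) -> int:
    """MACs of a standard convolution: Dk²·M·N per output pixel."""
    return c.dk * c.dk * c.m * c.n * c.df_out * c.df_out


def flops_depthwise_separable(c: ConvSpec) -> int:
    """MACs of the depthwise + pointwise factorization of ``c``.

    Depthwise: Dk²·M per output pixel; pointwise: M·N per output pixel.
    """
    area = c.df_out * c.df_out
    return c.dk * c.dk * c.m * area + c.m * c.n * area


def cost_ratio(dk: int, n: int) -> float:
    """Separable/standard MAC ratio ``1/N + 1/Dk²``.

    For a 3×3 kernel with a few hundred output filters this is ≈ 1/9, i.e.
    an 8–9× reduction in computation.
    """
    if dk < 1 or n < 1:
        raise ValueError("dk and n must be positive")
    return 1.0 / n + 1.0 / (dk * dk)


def _c(base: int, width: float) -> int:
    return max(1, int(round(base * width)))


def build_backbone(
    name: str,
    num_classes: int,
    width_multiplier: float = 1.0,
    input_size: tuple = (32, 32, 3),
) -> ModelSpec:
    """Build a desk-scale backbone spec.

    ``width_multiplier`` scales every channel count (minimum 1), the standard
    lever for trading accuracy against compute on small devices.
    """
    if width_multiplier <= 0:
        raise ValueError("width_multiplier must be > 0")
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    w = width_multiplier
    if name == "alexnet_s":
        # Larger first kernel, aggressive pooling, pointwise feature layer.
        blocks = [
            Conv("c1", _c(16, w), kernel=5),
            Pool(),
            Conv("c2", _c(32, w), kernel=3),
            Pool(),
            Conv("c3", _c(64, w), kernel=3),
            Pool(),
            Conv("feat", _c(128, w), kernel=1, kind="pointwise"),
            GlobalAvgPool(),
            Dense("head", num_classes),
        ]
    elif name == "vgg_s":
        # Stacked small 3×3 kernels only.
        blocks = [
            Conv("c1", _c(16, w)),
            Conv("c2", _c(16, w)),
            Pool(),
            Conv("c3", _c(32, w)),
            Conv("c4", _c(32, w)),
            Pool(),
            Conv("c5", _c(64, w)),
            Pool(),
            GlobalAvgPool(),
            Dense("head", num_classes),
        ]
    elif name == "googlenet_s":
        blocks = [
            Conv("stem", _c(16, w)),
            Pool(),
            Inception("inc1", _c(8, w), _c(16, w), _c(8, w)),
            Pool(),
            Inception("inc2", _c(16, w), _c(32, w), _c(16, w)),
            Conv("feat", _c(128, w), kernel=1, kind="pointwise"),
            GlobalAvgPool(),
            Dense("head", num_classes),
        ]
    elif name == "resnet_s":
        blocks = [
            Conv("stem", _c(16, w)),
            Residual("res1", _c(16, w)),
            Conv("down1", _c(32, w), stride=2),
            Residual("res2", _c(32, w)),
            Conv("down2", _c(64, w), stride=2),
            Residual("res3", _c(64, w)),
            GlobalAvgPool(),
            Dense("head", num_classes),
        ]
    else:
        raise ValueError(f"unknown backbone name {name!r}")
    spec = ModelSpec(name=name, input_size=input_size, num_classes=num_classes, blocks=blocks)
    spec.validate()
    return spec


def _separate(conv: Conv) -> List[Conv]:
    """Rewrite a standard Dk>1 conv as depthwise + pointwise."""
    return [
        Conv(conv.name + "_dw", kernel=conv.kernel, stride=conv.stride, kind="depthwise"),
        Conv(conv.name + "_pw", conv.out_channels, kernel=1, kind="pointwise",
             activation=conv.activation),
    ]


def lighten(spec: ModelSpec) -> ModelSpec:
    """Apply the lightweighting rewrites; warn and return input if nothing applies."""
    shapes = infer_shapes(spec)
    in_shapes = [spec.input_size] + shapes[:-1]
    blocks = list(spec.blocks)
    changed = False

    # Head redesign: pointwise conv directly before GAP moves after it, and a
    # pointwise projection conv immediately preceding it is dropped.
    for i in range(len(blocks) - 1):
        blk, nxt = blocks[i], blocks[i + 1]
        if isinstance(blk, Conv) and blk.kind == "pointwise" and isinstance(nxt, GlobalAvgPool):
            h_in = in_shapes[i][0]
            if h_in > 1:
                prefix = blocks[: i]
                if prefix and isinstance(prefix[-1], Conv) and prefix[-1].kind == "pointwise":
                    prefix = prefix[:-1]  # projection layer no longer needed
                blocks = prefix + [nxt, blk] + blocks[i + 2:]
                changed = True
            break

    shapes = None  # invalidated; recompute per-block input widths below
    tmp = ModelSpec(spec.name, spec.input_size, spec.num_classes, blocks)
    in_shapes = [spec.input_size] + infer_shapes(tmp)[:-1]

    out_blocks: List[object] = []
    for blk, shape_in in zip(blocks, in_shapes):
        if isinstance(blk, Conv) and blk.kind == "standard" and blk.kernel > 1:
            out_blocks.extend(_separate(blk))
            changed = True
        elif isinstance(blk, Residual):
            c_in = shape_in[2]
            out_blocks.append(InvertedResidual(blk.name, out_channels=c_in, expansion=6, stride=1))
            changed = True
        elif isinstance(blk, Inception) and not blk.separable:
            out_blocks.append(replace(blk, separable=True))
            changed = True
        else:
            out_blocks.append(blk)

    if not changed:
        warnings.warn(f"spec {spec.name!r} is already lightweight", stacklevel=2)
        return spec
    light = ModelSpec(
        name=spec.name + "_light",
        input_size=spec.input_size,
        num_classes=spec.num_classes,
        blocks=out_blocks,
    )
    light.validate()
    return light
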