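"""Architecture intermediate representation (IR) for small image classifiers.

Both the standard backbones and their lightweight rewrites are expressed as a
:class:`ModelSpec`: an ordered list of blocks (convolutions, pooling, residual
and inception-style composites, inverted residuals, a global-average-pool and
a single dense classifier head).  The IR is purely structural — parameters
live in a separate flat ``dict`` keyed by layer name (see :mod:`fedprune.graph`)
— which is what makes structured filter pruning and partial aggregation of
heterogeneous submodels straightforward.

Shape inference (:func:`infer_shapes`) validates that a spec chains
consistently and is reused by the analytic parameter/MAC accounting.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import List, Optional, Tuple

__all__ = [
    "Conv",
    "Pool",
    "GlobalAvgPool",
    "Dense",
    "Residual",
    "Inception",
    "InvertedResidual",
    "ModelSpec",
    "conv_out",
    "infer_shapes",
    "spec_to_json",
    "spec_from_json",
]


@dataclass
class Conv:
    """A convolution followed by batch norm and an activation.

    ``kind`` is one of ``standard`` (dense Dk×Dk×M×N kernel), ``depthwise``
    (one Dk×Dk filter per input channel, output channels == input channels;
    ``out_channels`` is ignored) or ``pointwise`` (1×1).  Padding is always
    ``kernel // 2`` ("same" for odd kernels).  Convolutions carry no additive
    bias; batch norm's beta provides the offset.
    """

    name: str
    out_channels: int = 0
    kernel: int = 3
    stride: int = 1
    kind: str = "standard"
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.kind not in ("standard", "depthwise", "pointwise"):
            raise ValueError(f"unknown conv kind {self.kind!r}")
        if self.kind == "pointwise" and self.kernel != 1:
            raise ValueError("pointwise conv requires kernel == 1")
        if self.kind != "depthwise" and self.out_channels < 1:
            raise ValueError("out_channels must be positive")
        if self.stride < 1 or self.kernel < 1:
            raise ValueError("kernel and stride must be positive")


@dataclass
class Pool:
    """Max pooling (non-overlapping by default)."""

    size: int = 2
    stride: int = 2


@dataclass
class GlobalAvgPool:
    """Spatial global average pooling down to 1×1."""


@dataclass
class Dense:
    """Fully connected layer; used only as the classifier head (after GAP)."""

    name: str
    units: int


@dataclass
class Residual:
    """Basic residual block: 3×3 conv (mid) → 3×3 conv (in), identity skip.

    Output = relu(x + F(x)); when the residual branch F is zero the block is
    an identity mapping on its (non-negative) input.  Input and output channel
    counts are equal by construction.
    """

    name: str
    mid_channels: int


@dataclass
class Inception:
    """Three parallel branches (1×1, 3×3, 5×5 convs) concatenated channelwise.

    With ``separable=True`` the 3×3 and 5×5 branches are depthwise-separable
    (set by the lightweighting rewriter).
    """

    name: str
    ch1: int
    ch3: int
    ch5: int
    separable: bool = False


@dataclass
class InvertedResidual:
    """Expansion → depthwise → linear projection, skip at stride 1 / equal width.

    1×1 conv expands k input channels to ``hidden_channels`` (default
    ``expansion * k``), a 3×3 depthwise conv (stride ``stride``) filters them,
    and a linear (identity-activation) 1×1 conv projects down to
    ``out_channels``.  The low-dimensional projection output deliberately has
    no nonlinearity (linear bottleneck).  The identity skip connection is
    present iff ``stride == 1`` and input width equals ``out_channels``.
    """

    name: str
    out_channels: int
    expansion: int = 6
    stride: int = 1
    hidden_channels: Optional[int] = None

    def __post_init__(self) -> None:
        if self.expansion < 1:
            raise ValueError("expansion factor must be >= 1")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")


Block = object  # any of the dataclasses above


@dataclass
class ModelSpec:
    """An ordered-block architecture description.

    Invariants: shapes chain consistently (checked by :func:`infer_shapes`)
    and there is exactly one classifier head (a final :class:`Dense`).
    """

    name: str
    input_size: Tuple[int, int, int]
    num_classes: int
    blocks: List[Block] = field(default_factory=list)

    def validate(self) -> None:
        heads = [b for b in self.blocks if isinstance(b, Dense)]
        if len(heads) != 1 or not isinstance(self.blocks[-1], Dense):
            raise ValueError("spec must end with exactly one Dense classifier head")
        if heads[0].units != self.num_classes:
            raise ValueError("head units must equal num_classes")
        infer_shapes(self)


def conv_out(size: int, kernel: int, stride: int) -> int:
    """Output spatial size of a 'same'-padded convolution."""
    pad = kernel // 2
    out = (size + 2 * pad - kernel) // stride + 1
    if out < 1:
        raise ValueError("non-positive feature-map size")
    return out


def infer_shapes(spec: ModelSpec) -> List[Tuple[int, int, int]]:
    """Per-block output shapes (H, W, C); raises on inconsistent chaining."""
    h, w, c = spec.input_size
    if h < 1 or w < 1 or c < 1:
        raise ValueError("input size must have positive H, W and channels")
    shapes: List[Tuple[int, int, int]] = []
    for blk in spec.blocks:
        if isinstance(blk, Conv):
            h2, w2 = conv_out(h, blk.kernel, blk.stride), conv_out(w, blk.kernel, blk.stride)
            c2 = c if blk.kind == "depthwise" else blk.out_channels
            h, w, c = h2, w2, c2
        elif isinstance(blk, Pool):
            h = (h - blk.size) // blk.stride + 1
            w = (w - blk.size) // blk.stride + 1
            if h < 1 or w < 1:
                raise ValueError("pooling produced a non-positive dimension")
        elif isinstance(blk, GlobalAvgPool):
            h, w = 1, 1
        elif isinstance(blk, Residual):
            if blk.mid_channels < 1:
                raise ValueError("residual mid_channels must be positive")
        elif isinstance(blk, Inception):
            if min(blk.ch1, blk.ch3, blk.ch5) < 1:
                raise ValueError("inception branch widths must be positive")
            c = blk.ch1 + blk.ch3 + blk.ch5
        elif isinstance(blk, InvertedResidual):
            hid = blk.hidden_channels or blk.expansion * c
            if hid < 1 or blk.out_channels < 1:
                raise ValueError("inverted residual widths must be positive")
            h = conv_out(h, 3, blk.stride)
            w = conv_out(w, 3, blk.stride)
            c = blk.out_channels
        elif isinstance(blk, Dense):
            if (h, w) != (1, 1):
                raise ValueError("dense head requires 1×1 spatial input (use GAP first)")
            c = blk.units
        else:
            raise TypeError(f"unknown block type {type(blk).__name__}")
        shapes.append((h, w, c))
    return shapes


_BLOCK_TYPES = {
    cls.__name__: cls
    for cls in (Conv, Pool, GlobalAvgPool, Dense, Residual, Inception, InvertedResidual)
}


def spec_to_json(spec: ModelSpec) -> str:
    payload = {
        "name": spec.name,
        "input_size": list(spec.input_size),
        "num_classes": spec.num_classes,
        "blocks": [dict(type=type(b).__name__, **asdict(b)) for b in spec.blocks],
    }
    return json.dumps(payload, indent=2)


def spec_from_json(text: str) -> ModelSpec:
    payload = json.loads(text)
    blocks = []
    for entry in payload["blocks"]:
        entry = dict(entry)
        cls = _BLOCK_TYPES[entry.pop("type")]
        blocks.append(cls(**entry))
    return ModelSpec(
        name=payload["name"],
        input_size=tuple(payload["input_size"]),
        num_classes=payload["num_classes"],
        blocks=blocks,
    )
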