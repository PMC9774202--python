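"""Execution plan, channel groups, and the parameter schema.

A :class:`ModelSpec` is flattened into a small DAG of primitive nodes
(``conv``, ``dwconv``, ``pool``, ``gap``, ``dense``, ``add``, ``relu``,
``concat``).  Every tensor in the DAG carries a *channel-group* reference:
the unit at which structured filter pruning operates.

* Each standard/pointwise conv output opens a new group, except where a
  residual-style skip forces the output back into the incoming trunk group
  (merge points are pruned jointly: the stem conv, every residual second
  conv and every skip-carrying inverted-residual projection share one group).
* Depthwise convs pass their group through untouched — removing a channel of
  the preceding pointwise conv removes the corresponding depthwise filter.
* Inception concatenations produce a composite ``("cat", ...)`` reference;
  consumers slice the concatenated index space with per-branch offsets.
* The network input and the classifier logits are non-prunable groups.

The same plan drives the NumPy engine (:mod:`fedprune.nn`), analytic
parameter/MAC accounting, parameter slicing for submodels, and the
scatter-based aggregation of partially overlapping client updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

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
)

__all__ = [
    "Group",
    "GroupRef",
    "PNode",
    "Plan",
    "build_plan",
    "ref_size",
    "resolve_indices",
    "group_sizes",
    "param_schema",
    "init_params",
    "count_costs",
    "slice_params",
]

GroupRef = Union[str, Tuple[str, Tuple[str, ...]]]  # "name" or ("cat", (refs...))


@dataclass
class Group:
    name: str
    size: int
    prunable: bool
    producers: List[str] = field(default_factory=list)  # conv node names


@dataclass
class PNode:
    id: int
    op: str  # input | conv | dwconv | pool | gap | dense | add | relu | concat
    inputs: Tuple[int, ...]
    name: Optional[str] = None
    kernel: int = 0
    stride: int = 1
    activation: str = "relu"
    in_ref: Optional[GroupRef] = None
    out_ref: Optional[GroupRef] = None
    hw: Tuple[int, int] = (0, 0)  # output spatial size
    pool_size: int = 0


@dataclass
class Plan:
    spec: ModelSpec
    nodes: List[PNode]
    groups: Dict[str, Group]
    out_id: int

    def prunable_groups(self) -> List[str]:
        return [g.name for g in self.groups.values() if g.prunable]


def ref_size(ref: GroupRef, groups: Dict[str, Group]) -> int:
    if isinstance(ref, str):
        return groups[ref].size
    return sum(groups[m].size for m in ref[1])


def resolve_indices(
    ref: GroupRef,
    groups: Dict[str, Group],
    mask: Optional[Dict[str, np.ndarray]] = None,
) -> np.ndarray:
    """Retained indices of a group reference within the full channel axis."""
    if isinstance(ref, str):
        g = groups[ref]
        if mask is not None and g.prunable and ref in mask:
            return np.asarray(mask[ref], dtype=np.intp)
        return np.arange(g.size, dtype=np.intp)
    parts = []
    offset = 0
    for member in ref[1]:
        parts.append(resolve_indices(member, groups, mask) + offset)
        offset += groups[member].size
    return np.concatenate(parts)


def build_plan(spec: ModelSpec) -> Plan:
    h0, w0, c0 = spec.input_size
    nodes: List[PNode] = []
    groups: Dict[str, Group] = {"input": Group("input", c0, prunable=False)}

    def add(**kw) -> int:
        node = PNode(id=len(nodes), **kw)
        nodes.append(node)
        return node.id

    def new_group(name: str, size: int, producer: str, prunable: bool = True) -> str:
        if name in groups:
            raise ValueError(f"duplicate group/layer name {name!r}")
        groups[name] = Group(name, size, prunable, producers=[producer])
        return name

    def conv_node(
        name: str,
        kernel: int,
        stride: int,
        activation: str,
        src: int,
        out_ref: GroupRef,
    ) -> int:
        n = nodes[src]
        hw = (conv_out(n.hw[0], kernel, stride), conv_out(n.hw[1], kernel, stride))
        if isinstance(out_ref, str) and name not in groups.get(out_ref, Group("", 0, False)).producers:
            if out_ref in groups:
                groups[out_ref].producers.append(name)
        return add(
            op="conv", inputs=(src,), name=name, kernel=kernel, stride=stride,
            activation=activation, in_ref=n.out_ref, out_ref=out_ref, hw=hw,
        )

    def dw_node(name: str, kernel: int, stride: int, activation: str, src: int) -> int:
        n = nodes[src]
        hw = (conv_out(n.hw[0], kernel, stride), conv_out(n.hw[1], kernel, stride))
        return add(
            op="dwconv", inputs=(src,), name=name, kernel=kernel, stride=stride,
            activation=activation, in_ref=n.out_ref, out_ref=n.out_ref, hw=hw,
        )

    cur = add(op="input", inputs=(), out_ref="input", hw=(h0, w0))

    for blk in spec.blocks:
        r = nodes[cur].out_ref
        if isinstance(blk, Conv):
            if blk.kind == "depthwise":
                cur = dw_node(blk.name, blk.kernel, blk.stride, blk.activation, cur)
            else:
                g = new_group(blk.name, blk.out_channels, blk.name)
                cur = conv_node(blk.name, blk.kernel, blk.stride, blk.activation, cur, g)
        elif isinstance(blk, Pool):
            n = nodes[cur]
            hw = ((n.hw[0] - blk.size) // blk.stride + 1, (n.hw[1] - blk.size) // blk.stride + 1)
            cur = add(op="pool", inputs=(cur,), stride=blk.stride, pool_size=blk.size,
                      in_ref=r, out_ref=r, hw=hw)
        elif isinstance(blk, GlobalAvgPool):
            cur = add(op="gap", inputs=(cur,), in_ref=r, out_ref=r, hw=(1, 1))
        elif isinstance(blk, Residual):
            t0 = cur
            g1 = new_group(blk.name + ".c1", blk.mid_channels, blk.name + ".c1")
            c1 = conv_node(blk.name + ".c1", 3, 1, "relu", t0, g1)
            c2 = conv_node(blk.name + ".c2", 3, 1, "linear", c1, r)
            s = add(op="add", inputs=(t0, c2), in_ref=r, out_ref=r, hw=nodes[c2].hw)
            cur = add(op="relu", inputs=(s,), in_ref=r, out_ref=r, hw=nodes[s].hw)
        elif isinstance(blk, Inception):
            t0 = cur
            b1g = new_group(blk.name + ".b1", blk.ch1, blk.name + ".b1")
            b1 = conv_node(blk.name + ".b1", 1, 1, "relu", t0, b1g)
            branches = [b1]
            for k, width in ((3, blk.ch3), (5, blk.ch5)):
                gname = f"{blk.name}.b{k}"
                g = new_group(gname, width, gname)
                if blk.separable:
                    d = dw_node(f"{gname}.dw", k, 1, "relu", t0)
                    branches.append(conv_node(gname, 1, 1, "relu", d, g))
                else:
                    branches.append(conv_node(gname, k, 1, "relu", t0, g))
            refs = tuple(nodes[b].out_ref for b in branches)
            cur = add(op="concat", inputs=tuple(branches), in_ref=r,
                      out_ref=("cat", refs), hw=nodes[b1].hw)
        elif isinstance(blk, InvertedResidual):
            t0 = cur
            k_in = ref_size(r, groups)
            hidden = blk.hidden_channels or blk.expansion * k_in
            ge = new_group(blk.name + ".exp", hidden, blk.name + ".exp")
            e = conv_node(blk.name + ".exp", 1, 1, "relu", t0, ge)
            d = dw_node(blk.name + ".dw", 3, blk.stride, "relu", e)
            skip = blk.stride == 1 and blk.out_channels == k_in
            if skip:
                p = conv_node(blk.name + ".proj", 1, 1, "linear", d, r)
                cur = add(op="add", inputs=(t0, p), in_ref=r, out_ref=r, hw=nodes[p].hw)
            else:
                gp = new_group(blk.name + ".proj", blk.out_channels, blk.name + ".proj")
                cur = conv_node(blk.name + ".proj", 1, 1, "linear", d, gp)
        elif isinstance(blk, Dense):
            g = new_group("logits", blk.units, blk.name, prunable=False)
            cur = add(op="dense", inputs=(cur,), name=blk.name, in_ref=r,
                      out_ref=g, hw=(1, 1))
        else:
            raise TypeError(f"unknown block type {type(blk).__name__}")

    return Plan(spec=spec, nodes=nodes, groups=groups, out_id=cur)


def group_sizes(plan: Plan, mask: Optional[Dict[str, np.ndarray]] = None) -> Dict[str, int]:
    return {
        name: len(resolve_indices(name, plan.groups, mask))
        for name in plan.groups
    }


@dataclass(frozen=True)
class ParamEntry:
    """One parameter array: its full shape and per-axis channel groups."""

    key: str
    shape: Tuple[int, ...]
    axis_refs: Dict[int, GroupRef]


def param_schema(plan: Plan) -> List[ParamEntry]:
    entries: List[ParamEntry] = []
    g = plan.groups
    for n in plan.nodes:
        if n.op == "conv":
            m, nn_ = ref_size(n.in_ref, g), ref_size(n.out_ref, g)
            entries.append(ParamEntry(f"{n.name}/W", (n.kernel, n.kernel, m, nn_),
                                      {2: n.in_ref, 3: n.out_ref}))
            entries.append(ParamEntry(f"{n.name}/gamma", (nn_,), {0: n.out_ref}))
            entries.append(ParamEntry(f"{n.name}/beta", (nn_,), {0: n.out_ref}))
        elif n.op == "dwconv":
            m = ref_size(n.in_ref, g)
            entries.append(ParamEntry(f"{n.name}/W", (n.kernel, n.kernel, m), {2: n.in_ref}))
            entries.append(ParamEntry(f"{n.name}/gamma", (m,), {0: n.in_ref}))
            entries.append(ParamEntry(f"{n.name}/beta", (m,), {0: n.in_ref}))
        elif n.op == "dense":
            m, nn_ = ref_size(n.in_ref, g), ref_size(n.out_ref, g)
            entries.append(ParamEntry(f"{n.name}/W", (m, nn_), {0: n.in_ref}))
            entries.append(ParamEntry(f"{n.name}/b", (nn_,), {}))
    return entries


def init_params(spec: ModelSpec, rng_seed: int) -> Dict[str, np.ndarray]:
    """He-initialized parameters for a spec (batch-norm gamma=1, beta=0)."""
    plan = build_plan(spec)
    rng = np.random.default_rng(rng_seed)
    params: Dict[str, np.ndarray] = {}
    for e in param_schema(plan):
        leaf = e.key.rsplit("/", 1)[1]
        if leaf == "W":
            fan_in = int(np.prod(e.shape[:-1])) if len(e.shape) > 1 else int(e.shape[0])
            if len(e.shape) == 3:  # depthwise: one k×k filter per channel
                fan_in = e.shape[0] * e.shape[1]
            params[e.key] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=e.shape)
        elif leaf == "gamma":
            params[e.key] = np.ones(e.shape)
        else:  # beta, b
            params[e.key] = np.zeros(e.shape)
    return params


def count_costs(spec: ModelSpec, mask: Optional[Dict[str, np.ndarray]] = None) -> Dict[str, int]:
    """Analytic parameter and MAC counts, optionally under a pruning mask.

    Conventions: conv and dense MACs only (batch norm, pooling and additions
    are not counted); batch-norm gamma/beta count as parameters.
    """
    plan = build_plan(spec)
    g = plan.groups

    def sz(ref: GroupRef) -> int:
        return len(resolve_indices(ref, g, mask))

    params = 0
    macs = 0
    for n in plan.nodes:
        area = n.hw[0] * n.hw[1]
        if n.op == "conv":
            m, nn_ = sz(n.in_ref), sz(n.out_ref)
            params += n.kernel * n.kernel * m * nn_ + 2 * nn_
            macs += n.kernel * n.kernel * m * nn_ * area
        elif n.op == "dwconv":
            m = sz(n.in_ref)
            params += n.kernel * n.kernel * m + 2 * m
            macs += n.kernel * n.kernel * m * area
        elif n.op == "dense":
            m, nn_ = sz(n.in_ref), sz(n.out_ref)
            params += m * nn_ + nn_
            macs += m * nn_
    return {"params": int(params), "macs": int(macs)}


def slice_params(
    spec: ModelSpec,
    params: Dict[str, np.ndarray],
    mask: Optional[Dict[str, np.ndarray]],
) -> Dict[str, np.ndarray]:
    """Extract the submodel parameter slices selected by a retained-index mask."""
    plan = build_plan(spec)
    out: Dict[str, np.ndarray] = {}
    for e in param_schema(plan):
        arr = params[e.key]
        if arr.shape != e.shape:
            raise ValueError(f"parameter {e.key} has shape {arr.shape}, expected {e.shape}")
        index = [np.arange(s, dtype=np.intp) for s in e.shape]
        for axis, ref in e.axis_refs.items():
            index[axis] = resolve_indices(ref, plan.groups, mask)
        out[e.key] = arr[np.ix_(*index)] if arr.ndim > 1 else arr[index[0]]
    return out
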