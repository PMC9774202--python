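"""Data-directed filter importance and resource-budgeted structured pruning.

Each client learns a per-filter importance score on its *local* data by
attaching trainable multiplicative gates (initialized at 1) to every prunable
channel group of the global model and minimizing the classification loss plus
an L1 penalty on the gates, with the backbone weights frozen.  A filter whose
activations do not help the local task keeps no gradient pressure to stay
large and is shrunk by the penalty, so the final gate magnitudes rank filters
by their usefulness *for that client's data distribution*.

Pruning retains, per prunable group, the ``ceil((1-rate) * F)`` filters of
highest importance (ties broken toward the lower index) and slices every
downstream consumer's input channels consistently.  The pruning rate for a
client is the smallest rate on a 0.05 grid whose analytically computed
parameter/MAC cost fits the client's resource budget; the rate is uniform
across prunable groups.  The classifier head, the input, and depthwise
filters (which follow their producing pointwise group) are never pruned;
channel sets shared across residual merge points are pruned jointly.

Masks serialize to JSON (group name → retained index list, plus rates).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graph import build_plan, count_costs, ref_size, slice_params
from .ir import Conv, Inception, InvertedResidual, ModelSpec, Residual
from .nn import Network, softmax_cross_entropy, _batches

__all__ = [
    "FilterImportance",
    "ResourceBudget",
    "PruningMask",
    "RATE_GRID",
    "learn_importance",
    "pruning_rate_for_budget",
    "make_mask",
    "apply_mask_to_spec",
    "prune",
]

#: Admissible uniform pruning rates.
RATE_GRID = tuple(round(0.05 * i, 2) for i in range(20))  # 0.00 .. 0.95


@dataclass
class FilterImportance:
    """Per prunable channel group, non-negative per-filter scores."""

    scores: Dict[str, np.ndarray]

    def validate(self, spec: ModelSpec) -> None:
        plan = build_plan(spec)
        for name in plan.prunable_groups():
            if name not in self.scores:
                raise ValueError(f"missing importance for group {name!r}")
            v = self.scores[name]
            if len(v) != plan.groups[name].size:
                raise ValueError(f"importance length mismatch for group {name!r}")
            if not np.all(np.isfinite(v)) or (v < 0).any():
                raise ValueError("importance scores must be finite and >= 0")

    def concat(self, normalize: bool = True) -> np.ndarray:
        parts = []
        for name in sorted(self.scores):
            v = np.asarray(self.scores[name], dtype=float)
            if normalize:
                norm = np.linalg.norm(v)
                if norm == 0:
                    raise ValueError(f"zero-norm importance vector for group {name!r}")
                v = v / norm
            parts.append(v)
        return np.concatenate(parts)


@dataclass(frozen=True)
class ResourceBudget:
    """Client resource ceiling; either bound may be left unset (None)."""

    max_params: Optional[int] = None
    max_macs: Optional[int] = None

    def __post_init__(self) -> None:
        for v in (self.max_params, self.max_macs):
            if v is not None and v <= 0:
                raise ValueError("budget values must be positive")

    def satisfied_by(self, costs: Dict[str, int]) -> bool:
        if self.max_params is not None and costs["params"] > self.max_params:
            return False
        if self.max_macs is not None and costs["macs"] > self.max_macs:
            return False
        return True


@dataclass
class PruningMask:
    """Retained filter indices per prunable group, plus pruning rates.

    ``pruning_rate`` is the realized aggregate rate
    ``1 - retained filters / total filters`` over prunable groups;
    ``nominal_rate`` is the grid rate that produced the mask.
    """

    retained: Dict[str, np.ndarray]
    pruning_rate: float
    nominal_rate: float

    def to_json(self) -> str:
        return json.dumps({
            "pruning_rate": self.pruning_rate,
            "nominal_rate": self.nominal_rate,
            "retained": {k: np.asarray(v).tolist() for k, v in self.retained.items()},
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PruningMask":
        d = json.loads(text)
        return cls(
            retained={k: np.asarray(v, dtype=np.intp) for k, v in d["retained"].items()},
            pruning_rate=d["pruning_rate"],
            nominal_rate=d["nominal_rate"],
        )

    def as_dict(self) -> Dict[str, np.ndarray]:
        return self.retained


def learn_importance(
    spec: ModelSpec,
    params: Dict[str, np.ndarray],
    client_data: Tuple[np.ndarray, np.ndarray],
    epochs: int = 1,
    rng_seed: int = 0,
    l1_lambda: float = 1e-4,
    gate_lr: float = 0.05,
    batch_size: int = 32,
) -> FilterImportance:
    """Learn per-filter importance from a client's local (X, y) shard.

    Only the gates are trained; the global model's weights are left
    untouched.  With ``epochs == 0`` every score is exactly 1 (the
    initialization).  Scores are the final gate magnitudes.
    """
    X, y = client_data
    if len(X) == 0:
        raise ValueError("empty client data")
    plan = build_plan(spec)
    gates = {g: np.ones(plan.groups[g].size) for g in plan.prunable_groups()}
    net = Network(spec, params, gates=gates)
    rng = np.random.default_rng(np.random.SeedSequence((rng_seed, 0xF117)))
    for _ in range(int(epochs)):
        for idx in _batches(len(X), batch_size, rng):
            logits = net.forward(X[idx])
            _, dlog = softmax_cross_entropy(logits, y[idx])
            _, ggrads = net.backward(dlog)
            for g in gates:
                gates[g] -= gate_lr * (ggrads[g] + l1_lambda * np.sign(gates[g]))
    return FilterImportance({g: np.abs(v) for g, v in gates.items()})


def _mask_for_rate(plan, rate: float, importance: Optional[FilterImportance]) -> Dict[str, np.ndarray]:
    retained = {}
    for g in plan.prunable_groups():
        size = plan.groups[g].size
        keep = max(1, math.ceil((1.0 - rate) * size))
        if importance is None:
            retained[g] = np.arange(keep, dtype=np.intp)
        else:
            scores = np.asarray(importance.scores[g], dtype=float)
            order = np.argsort(-scores, kind="stable")  # ties -> lower index first
            retained[g] = np.sort(order[:keep]).astype(np.intp)
    return retained


def make_mask(spec: ModelSpec, importance: Optional[FilterImportance], rate: float) -> PruningMask:
    """Top-importance retained-index mask at a uniform pruning rate."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("pruning rate must be in [0, 1)")
    plan = build_plan(spec)
    if importance is not None:
        importance.validate(spec)
    retained = _mask_for_rate(plan, rate, importance)
    total = sum(plan.groups[g].size for g in retained)
    kept = sum(len(v) for v in retained.values())
    realized = 1.0 - kept / total if total else 0.0
    return PruningMask(retained=retained, pruning_rate=realized, nominal_rate=rate)


def pruning_rate_for_budget(spec: ModelSpec, budget: ResourceBudget) -> float:
    """Smallest grid rate whose analytic pruned cost satisfies the budget."""
    plan = build_plan(spec)
    for rate in RATE_GRID:
        mask = _mask_for_rate(plan, rate, None)
        if budget.satisfied_by(count_costs(spec, mask)):
            return rate
    minimal = {g: np.arange(1, dtype=np.intp) for g in plan.prunable_groups()}
    if not budget.satisfied_by(count_costs(spec, minimal)):
        raise ValueError("budget below minimal submodel")
    raise ValueError("budget not attainable on the pruning-rate grid")


def apply_mask_to_spec(spec: ModelSpec, mask: PruningMask) -> ModelSpec:
    """The pruned architecture: channel counts reduced to the retained sets."""
    plan = build_plan(spec)
    retained = mask.retained

    def kept(group_name: str) -> int:
        if group_name in retained:
            return len(retained[group_name])
        return plan.groups[group_name].size

    def ref_kept(ref) -> int:
        if isinstance(ref, str):
            return kept(ref)
        return sum(kept(m) for m in ref[1])

    blocks = []
    cur_ref = "input"
    for blk in spec.blocks:
        if isinstance(blk, Conv):
            if blk.kind == "depthwise":
                blocks.append(replace(blk))
            else:
                blocks.append(replace(blk, out_channels=kept(blk.name)))
                cur_ref = blk.name
        elif isinstance(blk, Residual):
            blocks.append(replace(blk, mid_channels=kept(blk.name + ".c1")))
        elif isinstance(blk, Inception):
            blocks.append(replace(
                blk,
                ch1=kept(blk.name + ".b1"),
                ch3=kept(blk.name + ".b3"),
                ch5=kept(blk.name + ".b5"),
            ))
            cur_ref = ("cat", (blk.name + ".b1", blk.name + ".b3", blk.name + ".b5"))
        elif isinstance(blk, InvertedResidual):
            k_in_full = ref_size(cur_ref, plan.groups)
            skip = blk.stride == 1 and blk.out_channels == k_in_full
            out = ref_kept(cur_ref) if skip else kept(blk.name + ".proj")
            blocks.append(replace(
                blk,
                out_channels=out,
                hidden_channels=kept(blk.name + ".exp"),
            ))
            if not skip:
                cur_ref = blk.name + ".proj"
        else:
            blocks.append(blk)
    sub = ModelSpec(spec.name + "_sub", spec.input_size, spec.num_classes, blocks)
    sub.validate()
    return sub


def prune(
    spec: ModelSpec,
    params: Dict[str, np.ndarray],
    importance: FilterImportance,
    rate: float,
) -> Tuple[ModelSpec, Dict[str, np.ndarray], PruningMask]:
    """Structurally prune the global model for one client.

    Returns the pruned architecture, its sliced parameters, and the mask.
    At ``rate == 0`` the submodel equals the input model and the mask retains
    every filter.
    """
    mask = make_mask(spec, importance, rate)
    sub_spec = apply_mask_to_spec(spec, mask)
    sub_params = slice_params(spec, params, mask.as_dict())
    return sub_spec, sub_params, mask
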