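"""Analytic resource accounting: parameters, MACs, and transfer bytes.

Hardware latency is out of scope for a desk-scale simulator; instead the
resource report states, per model, the analytically counted parameters and
multiply-accumulates, the per-round upload volume (4 bytes per transmitted
parameter), and — when a lightweight variant is present — the reduction
ratios relative to the original.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .graph import build_plan, count_costs, ref_size
from .ir import ModelSpec

__all__ = ["per_layer_costs", "ResourceReport", "resource_report"]

BYTES_PER_PARAM = 4


def per_layer_costs(spec: ModelSpec) -> List[Dict[str, object]]:
    """Per-parameterized-layer parameter and MAC table."""
    plan = build_plan(spec)
    rows = []
    for n in plan.nodes:
        if n.op not in ("conv", "dwconv", "dense"):
            continue
        area = n.hw[0] * n.hw[1]
        if n.op == "conv":
            m, nn_ = ref_size(n.in_ref, plan.groups), ref_size(n.out_ref, plan.groups)
            params = n.kernel * n.kernel * m * nn_ + 2 * nn_
            macs = n.kernel * n.kernel * m * nn_ * area
        elif n.op == "dwconv":
            m = ref_size(n.in_ref, plan.groups)
            params = n.kernel * n.kernel * m + 2 * m
            macs = n.kernel * n.kernel * m * area
        else:
            m, nn_ = ref_size(n.in_ref, plan.groups), ref_size(n.out_ref, plan.groups)
            params = m * nn_ + nn_
            macs = m * nn_
        rows.append({"layer": n.name, "op": n.op, "kernel": n.kernel,
                     "out_hw": list(n.hw), "params": int(params), "macs": int(macs)})
    return rows


@dataclass
class ResourceReport:
    """Model-level cost summary, optionally versus an original model."""

    model: str
    params: int
    macs: int
    upload_bytes_per_round: int
    original_params: Optional[int] = None
    original_macs: Optional[int] = None

    @property
    def param_ratio(self) -> Optional[float]:
        if self.original_params:
            return self.params / self.original_params
        return None

    @property
    def mac_ratio(self) -> Optional[float]:
        if self.original_macs:
            return self.macs / self.original_macs
        return None

    def to_json(self) -> str:
        d = {
            "model": self.model,
            "params": self.params,
            "macs": self.macs,
            "upload_bytes_per_round": self.upload_bytes_per_round,
        }
        if self.original_params is not None:
            d["original_params"] = self.original_params
            d["original_macs"] = self.original_macs
            d["param_ratio"] = round(self.param_ratio, 4)
            d["mac_ratio"] = round(self.mac_ratio, 4)
        return json.dumps(d, indent=2)


def resource_report(
    spec: ModelSpec,
    transmitted_params: Optional[int] = None,
    original: Optional[ModelSpec] = None,
) -> ResourceReport:
    """Build the report; ``transmitted_params`` defaults to the full model."""
    costs = count_costs(spec)
    sent = transmitted_params if transmitted_params is not None else costs["params"]
    orig = count_costs(original) if original is not None else None
    return ResourceReport(
        model=spec.name,
        params=costs["params"],
        macs=costs["macs"],
        upload_bytes_per_round=BYTES_PER_PARAM * sent,
        original_params=orig["params"] if orig else None,
        original_macs=orig["macs"] if orig else None,
    )
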