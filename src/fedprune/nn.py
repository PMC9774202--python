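"""A small NumPy engine for training and evaluating plan-compiled networks.

Forward and backward passes are written directly against the execution plan
of :mod:`fedprune.graph`.  Supported ops: standard/pointwise convolution
(kernel-offset matmul formulation), depthwise convolution, batch norm,
ReLU, non-overlapping max pooling, global average pooling, dense, residual
addition and channel concatenation.

Batch norm always normalizes with the statistics of the current batch (no
running averages): evaluation therefore uses moderately sized, deterministic
batches.  This keeps the trainable parameter set exactly equal to the set
that federated aggregation exchanges, and makes zero-learning-rate training
an exact no-op.

Per-filter multiplicative gates (used to learn data-directed filter
importance) attach to prunable channel groups and multiply the activated
output of each producing convolution; their gradients are accumulated
alongside the parameter gradients.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graph import Plan, build_plan, param_schema, resolve_indices
from .ir import ModelSpec

__all__ = ["Network", "softmax_cross_entropy", "train_sgd", "evaluate", "predict"]

_BN_EPS = 1e-5


def _pad_hw(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))


class Network:
    """Executable network: an execution plan plus a flat parameter dict.

    ``mask`` (group name → retained indices) compiles the pruned submodel:
    ``params`` must then hold the correspondingly sliced arrays.  ``gates``
    (group name → per-channel multipliers) enables importance learning.
    """

    def __init__(
        self,
        spec: ModelSpec,
        params: Dict[str, np.ndarray],
        mask: Optional[Dict[str, np.ndarray]] = None,
        gates: Optional[Dict[str, np.ndarray]] = None,
    ) -> None:
        self.spec = spec
        self.plan: Plan = build_plan(spec)
        self.params = params
        self.mask = mask
        self.gates = gates
        self._sizes = {
            name: len(resolve_indices(name, self.plan.groups, mask))
            for name in self.plan.groups
        }
        for e in param_schema(self.plan):
            want = list(e.shape)
            for axis, ref in e.axis_refs.items():
                want[axis] = self._ref_len(ref)
            if e.key not in params:
                raise ValueError(f"missing parameter {e.key}")
            if tuple(want) != params[e.key].shape:
                raise ValueError(
                    f"parameter {e.key}: shape {params[e.key].shape}, expected {tuple(want)}"
                )
        self._vals: List[np.ndarray] = []
        self._cache: List[dict] = []

    def _ref_len(self, ref) -> int:
        if isinstance(ref, str):
            return self._sizes[ref]
        return sum(self._sizes[m] for m in ref[1])

    def _gate_for(self, node) -> Optional[np.ndarray]:
        if self.gates is None:
            return None
        ref = node.out_ref
        if isinstance(ref, str) and ref in self.gates:
            return self.gates[ref]
        return None

    # ------------------------------------------------------------------ forward
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Run a (B, H, W, C) batch through the network; returns logits."""
        n_nodes = len(self.plan.nodes)
        self._vals = [None] * n_nodes
        self._cache = [None] * n_nodes
        for node in self.plan.nodes:
            if node.op == "input":
                out = np.asarray(x, dtype=np.float64)
            elif node.op == "conv":
                out = self._conv_fwd(node, self._vals[node.inputs[0]])
            elif node.op == "dwconv":
                out = self._dwconv_fwd(node, self._vals[node.inputs[0]])
            elif node.op == "pool":
                out = self._pool_fwd(node, self._vals[node.inputs[0]])
            elif node.op == "gap":
                src = self._vals[node.inputs[0]]
                self._cache[node.id] = {"hw": src.shape[1:3]}
                out = src.mean(axis=(1, 2), keepdims=True)
            elif node.op == "add":
                out = self._vals[node.inputs[0]] + self._vals[node.inputs[1]]
            elif node.op == "relu":
                src = self._vals[node.inputs[0]]
                out = np.maximum(src, 0.0)
                self._cache[node.id] = {"mask": src > 0}
            elif node.op == "concat":
                parts = [self._vals[i] for i in node.inputs]
                self._cache[node.id] = {"widths": [p.shape[3] for p in parts]}
                out = np.concatenate(parts, axis=3)
            elif node.op == "dense":
                src = self._vals[node.inputs[0]]
                flat = src.reshape(src.shape[0], -1)
                W = self.params[f"{node.name}/W"]
                b = self.params[f"{node.name}/b"]
                self._cache[node.id] = {"flat": flat, "shape": src.shape}
                out = flat @ W + b
            else:  # pragma: no cover
                raise RuntimeError(f"unknown op {node.op}")
            self._vals[node.id] = out
        return self._vals[self.plan.out_id]

    def _bn_act(self, node, z: np.ndarray) -> Tuple[np.ndarray, dict]:
        gamma = self.params[f"{node.name}/gamma"]
        beta = self.params[f"{node.name}/beta"]
        mu = z.mean(axis=(0, 1, 2))
        var = z.var(axis=(0, 1, 2))
        inv = 1.0 / np.sqrt(var + _BN_EPS)
        zhat = (z - mu) * inv
        h = gamma * zhat + beta
        cache = {"zhat": zhat, "inv": inv, "gamma": gamma}
        if node.activation == "relu":
            cache["act_mask"] = h > 0
            h = np.maximum(h, 0.0)
        gate = self._gate_for(node)
        if gate is not None:
            cache["pre_gate"] = h
            h = h * gate
        return h, cache

    def _conv_fwd(self, node, x: np.ndarray) -> np.ndarray:
        W = self.params[f"{node.name}/W"]
        k, s = node.kernel, node.stride
        pad = k // 2
        xp = _pad_hw(x, pad)
        Hs, Ws = node.hw
        z = None
        for a in range(k):
            for b in range(k):
                xs = xp[:, a : a + s * Hs : s, b : b + s * Ws : s, :]
                v = xs @ W[a, b]
                z = v if z is None else z + v
        h, cache = self._bn_act(node, z)
        cache.update({"xp": xp, "pad": pad, "xshape": x.shape})
        self._cache[node.id] = cache
        return h

    def _dwconv_fwd(self, node, x: np.ndarray) -> np.ndarray:
        W = self.params[f"{node.name}/W"]
        k, s = node.kernel, node.stride
        pad = k // 2
        xp = _pad_hw(x, pad)
        Hs, Ws = node.hw
        z = None
        for a in range(k):
            for b in range(k):
                xs = xp[:, a : a + s * Hs : s, b : b + s * Ws : s, :]
                v = xs * W[a, b]
                z = v if z is None else z + v
        h, cache = self._bn_act(node, z)
        cache.update({"xp": xp, "pad": pad, "xshape": x.shape})
        self._cache[node.id] = cache
        return h

    def _pool_fwd(self, node, x: np.ndarray) -> np.ndarray:
        sz = node.pool_size
        if sz != node.stride:
            raise NotImplementedError("only non-overlapping pooling is supported")
        B, H, W, C = x.shape
        Ho, Wo = node.hw
        xc = x[:, : Ho * sz, : Wo * sz, :]
        r = xc.reshape(B, Ho, sz, Wo, sz, C).transpose(0, 1, 3, 5, 2, 4)
        r = r.reshape(B, Ho, Wo, C, sz * sz)
        idx = r.argmax(axis=4)
        out = np.take_along_axis(r, idx[..., None], axis=4)[..., 0]
        self._cache[node.id] = {"idx": idx, "xshape": x.shape}
        return out

    # ----------------------------------------------------------------- backward
    def backward(self, d_logits: np.ndarray) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
        """Backprop from logits gradient; returns (param grads, gate grads)."""
        grads: Dict[str, np.ndarray] = {}
        gate_grads: Dict[str, np.ndarray] = {}
        if self.gates is not None:
            gate_grads = {g: np.zeros_like(v) for g, v in self.gates.items()}
        d_vals: List[Optional[np.ndarray]] = [None] * len(self.plan.nodes)
        d_vals[self.plan.out_id] = np.asarray(d_logits, dtype=np.float64)

        for node in reversed(self.plan.nodes):
            d = d_vals[node.id]
            if d is None or node.op == "input":
                continue
            if node.op == "conv":
                dx = self._conv_bwd(node, d, grads, gate_grads)
                self._accum(d_vals, node.inputs[0], dx)
            elif node.op == "dwconv":
                dx = self._dwconv_bwd(node, d, grads, gate_grads)
                self._accum(d_vals, node.inputs[0], dx)
            elif node.op == "pool":
                self._accum(d_vals, node.inputs[0], self._pool_bwd(node, d))
            elif node.op == "gap":
                hw = self._cache[node.id]["hw"]
                dx = np.broadcast_to(d / (hw[0] * hw[1]),
                                     (d.shape[0], hw[0], hw[1], d.shape[3])).copy()
                self._accum(d_vals, node.inputs[0], dx)
            elif node.op == "add":
                self._accum(d_vals, node.inputs[0], d)
                self._accum(d_vals, node.inputs[1], d)
            elif node.op == "relu":
                self._accum(d_vals, node.inputs[0], d * self._cache[node.id]["mask"])
            elif node.op == "concat":
                widths = self._cache[node.id]["widths"]
                off = 0
                for src, wdt in zip(node.inputs, widths):
                    self._accum(d_vals, src, d[..., off : off + wdt])
                    off += wdt
            elif node.op == "dense":
                cache = self._cache[node.id]
                flat = cache["flat"]
                W = self.params[f"{node.name}/W"]
                grads[f"{node.name}/W"] = flat.T @ d
                grads[f"{node.name}/b"] = d.sum(axis=0)
                self._accum(d_vals, node.inputs[0], (d @ W.T).reshape(cache["shape"]))
            d_vals[node.id] = None  # release
        return grads, gate_grads

    @staticmethod
    def _accum(d_vals, idx, d):
        if d_vals[idx] is None:
            d_vals[idx] = d
        else:
            d_vals[idx] = d_vals[idx] + d

    def _bn_act_bwd(self, node, d, cache, grads, gate_grads) -> np.ndarray:
        gate = self._gate_for(node)
        if gate is not None:
            ref = node.out_ref
            gate_grads[ref] += (d * cache["pre_gate"]).sum(axis=(0, 1, 2))
            d = d * gate
        if node.activation == "relu":
            d = d * cache["act_mask"]
        zhat, inv, gamma = cache["zhat"], cache["inv"], cache["gamma"]
        axes = (0, 1, 2)
        grads[f"{node.name}/gamma"] = (d * zhat).sum(axis=axes)
        grads[f"{node.name}/beta"] = d.sum(axis=axes)
        dzhat = d * gamma
        n = d.shape[0] * d.shape[1] * d.shape[2]
        dz = (inv / n) * (
            n * dzhat - dzhat.sum(axis=axes) - zhat * (dzhat * zhat).sum(axis=axes)
        )
        return dz

    def _conv_bwd(self, node, d, grads, gate_grads) -> np.ndarray:
        cache = self._cache[node.id]
        dz = self._bn_act_bwd(node, d, cache, grads, gate_grads)
        W = self.params[f"{node.name}/W"]
        k, s = node.kernel, node.stride
        xp, pad = cache["xp"], cache["pad"]
        Hs, Ws = node.hw
        dW = np.zeros_like(W)
        dxp = np.zeros_like(xp)
        for a in range(k):
            for b in range(k):
                sl = np.s_[:, a : a + s * Hs : s, b : b + s * Ws : s, :]
                xs = xp[sl]
                dW[a, b] = np.tensordot(xs, dz, axes=([0, 1, 2], [0, 1, 2]))
                dxp[sl] += dz @ W[a, b].T
        grads[f"{node.name}/W"] = dW
        H, Wd = cache["xshape"][1:3]
        return dxp[:, pad : pad + H, pad : pad + Wd, :]

    def _dwconv_bwd(self, node, d, grads, gate_grads) -> np.ndarray:
        cache = self._cache[node.id]
        dz = self._bn_act_bwd(node, d, cache, grads, gate_grads)
        W = self.params[f"{node.name}/W"]
        k, s = node.kernel, node.stride
        xp, pad = cache["xp"], cache["pad"]
        Hs, Ws = node.hw
        dW = np.zeros_like(W)
        dxp = np.zeros_like(xp)
        for a in range(k):
            for b in range(k):
                sl = np.s_[:, a : a + s * Hs : s, b : b + s * Ws : s, :]
                xs = xp[sl]
                dW[a, b] = (xs * dz).sum(axis=(0, 1, 2))
                dxp[sl] += dz * W[a, b]
        grads[f"{node.name}/W"] = dW
        H, Wd = cache["xshape"][1:3]
        return dxp[:, pad : pad + H, pad : pad + Wd, :]

    def _pool_bwd(self, node, d) -> np.ndarray:
        cache = self._cache[node.id]
        idx = cache["idx"]
        B, H, W, C = cache["xshape"]
        sz = node.pool_size
        Ho, Wo = idx.shape[1], idx.shape[2]
        r = np.zeros((B, Ho, Wo, C, sz * sz))
        np.put_along_axis(r, idx[..., None], d[..., None], axis=4)
        r = r.reshape(B, Ho, Wo, C, sz, sz).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros((B, H, W, C))
        dx[:, : Ho * sz, : Wo * sz, :] = r.reshape(B, Ho * sz, Wo * sz, C)
        return dx


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.log(p[np.arange(n), labels] + 1e-300).mean())
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return loss, d / n


def _batches(n: int, batch_size: int, rng: Optional[np.random.Generator]) -> List[np.ndarray]:
    idx = np.arange(n)
    if rng is not None:
        rng.shuffle(idx)
    if n <= batch_size:
        return [idx]
    nb = n // batch_size  # drop the (shuffled) remainder
    return [idx[i * batch_size : (i + 1) * batch_size] for i in range(nb)]


def train_sgd(
    net: Network,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int,
    lr: float,
    batch_size: int = 32,
    momentum: float = 0.9,
    rng: Optional[np.random.Generator] = None,
    steps: Optional[int] = None,
) -> float:
    """Mini-batch SGD with momentum on the network's parameters, in place.

    With ``steps`` set, exactly that many mini-batch updates are performed
    (reshuffling whenever the data is exhausted) regardless of ``epochs``;
    otherwise ``epochs`` full passes are made.  Returns the mean training
    loss over the last pass (0.0 when no update is made, in which case the
    parameters are untouched).
    """
    if len(X) == 0:
        raise ValueError("empty training data")
    vel = {k: np.zeros_like(v) for k, v in net.params.items()}

    def one_batch(idx) -> float:
        logits = net.forward(X[idx])
        loss, dlog = softmax_cross_entropy(logits, y[idx])
        if not np.isfinite(loss):
            raise FloatingPointError("training loss diverged (non-finite)")
        grads, _ = net.backward(dlog)
        for k, g in grads.items():
            vel[k] = momentum * vel[k] - lr * g
            net.params[k] += vel[k]
        return loss

    losses: List[float] = []
    if steps is not None:
        done = 0
        while done < steps:
            for idx in _batches(len(X), batch_size, rng):
                losses.append(one_batch(idx))
                done += 1
                if done >= steps:
                    break
        return float(np.mean(losses)) if losses else 0.0
    last = 0.0
    for _ in range(int(epochs)):
        losses = [one_batch(idx) for idx in _batches(len(X), batch_size, rng)]
        last = float(np.mean(losses))
    return last


def predict(net: Network, X: np.ndarray, batch_size: int = 200) -> np.ndarray:
    """Deterministic batched argmax predictions.

    Because batch norm normalizes with the statistics of the evaluated batch,
    samples are processed in a fixed seeded permutation (evaluation sets are
    often stored class-sorted, and class-homogeneous batches would shift the
    normalization statistics); predictions are returned in input order.
    """
    n = len(X)
    if n == 0:
        return np.zeros(0, dtype=int)
    perm = np.random.default_rng(0).permutation(n)
    n_chunks = max(1, int(np.ceil(n / batch_size)))
    preds = np.zeros(n, dtype=int)
    for idx in np.array_split(perm, n_chunks):
        preds[idx] = net.forward(X[idx]).argmax(axis=1)
    return preds


def evaluate(net: Network, X: np.ndarray, y: np.ndarray, batch_size: int = 200) -> float:
    """Classification accuracy under deterministic batching."""
    return float((predict(net, X, batch_size) == y).mean())
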