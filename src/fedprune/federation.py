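"""Dual-ended personalized federated learning round loop.

One communication round:

1. the server distributes the global model;
2. each client (on the importance-refresh schedule) learns filter importance
   on its local shard, derives its pruning rate from its resource budget,
   and prunes the global model to a personal submodel;
3. clients train their submodels locally (mini-batch SGD) in parallel —
   simulated in-process — and upload the updated slices;
4. the server scales each client's contribution by
   ``w_k = n_samples_k * (1 + pruning_rate_k)`` and takes the weighted
   average of the *overlapping* parameter coordinates; coordinates retained
   by no client keep their previous global value;
5. the server computes pairwise client similarity (cosine of the
   L2-normalized importance vectors), groups clients by single linkage at a
   threshold, and re-selects each group member's retained indices from the
   group's shared importance ranking, so similar clients converge to nested
   masks while dissimilar clients keep individualized masks;
6. the full global model is evaluated on the held-out test set.

The ``1 + pruning_rate`` scaling up-weights heavily pruned clients on the few
coordinates they still cover and degrades exactly to sample-count-weighted
FedAvg when nobody prunes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graph import build_plan, count_costs, param_schema, resolve_indices, slice_params
from .ir import ModelSpec
from .metrics import confusion, accuracy as cm_accuracy, precision as cm_precision, \
    recall as cm_recall
from .nn import Network, predict, train_sgd
from .pruning import (
    FilterImportance,
    PruningMask,
    ResourceBudget,
    learn_importance,
    make_mask,
    prune,
    pruning_rate_for_budget,
)

__all__ = [
    "ClientState",
    "GlobalModel",
    "RoundLog",
    "FederatedConfig",
    "local_update",
    "aggregate",
    "client_similarity",
    "tune_submodels",
    "run_federated",
    "train_centralized",
]


@dataclass
class ClientState:
    """Everything the simulator tracks for one participating client."""

    client_id: int
    data: Tuple[np.ndarray, np.ndarray]  # (X, y) local shard
    budget: ResourceBudget = field(default_factory=ResourceBudget)
    importance: Optional[FilterImportance] = None
    mask: Optional[PruningMask] = None
    sub_params: Optional[Dict[str, np.ndarray]] = None
    pruning_rate: float = 0.0

    @property
    def n_samples(self) -> int:
        return len(self.data[0])


@dataclass
class GlobalModel:
    spec: ModelSpec
    params: Dict[str, np.ndarray]
    round: int = 0


@dataclass
class RoundLog:
    """Per-round record: client stats, global test metrics, similarity."""

    round: int
    client_rates: List[float]
    client_losses: List[float]
    client_samples: List[int]
    accuracy: float
    precision: float
    recall: float
    similarity: List[List[float]]

    def to_dict(self) -> dict:
        return {
            "round": self.round,
            "client_rates": self.client_rates,
            "client_losses": self.client_losses,
            "client_samples": self.client_samples,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "similarity": self.similarity,
        }


@dataclass
class FederatedConfig:
    rounds: int = 5
    local_epochs: int = 1
    local_steps: Optional[int] = 16  # per-round optimizer steps; None -> epochs
    importance_epochs: int = 1
    lr: float = 0.2
    lr_decay: float = 0.6  # per-round multiplicative decay
    batch_size: int = 48
    momentum: float = 0.9
    tau: float = 0.9
    refresh_period: int = 10
    gate_lr: float = 0.05
    l1_lambda: float = 1e-4
    eval_batch: int = 200
    seed: int = 0

    def round_lr(self, round_idx: int) -> float:
        return self.lr * self.lr_decay ** (round_idx - 1)


def _round_rng(seed: int, round_idx: int, client_id: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, round_idx, client_id, purpose)))


def local_update(
    client: ClientState,
    global_model: GlobalModel,
    epochs: int,
    lr: float,
    rng_seed: Optional[np.random.Generator] = None,
    batch_size: int = 32,
    momentum: float = 0.9,
    steps: Optional[int] = None,
) -> Tuple[Dict[str, np.ndarray], float]:
    """Train a client's submodel starting from the global parameter slices.

    Local work is ``epochs`` full passes, or exactly ``steps`` mini-batch
    updates when ``steps`` is set.  Returns the updated slices and the mean
    training loss.  ``epochs == 0`` (with ``steps`` unset) returns the sliced
    global parameters unchanged; ``lr == 0`` performs the passes but moves
    nothing.
    """
    mask = client.mask.as_dict() if client.mask is not None else None
    sub_params = slice_params(global_model.spec, global_model.params, mask)
    net = Network(global_model.spec, sub_params, mask=mask)
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else \
        np.random.default_rng(rng_seed)
    X, y = client.data
    try:
        loss = train_sgd(net, X, y, epochs=epochs, lr=lr, batch_size=batch_size,
                         momentum=momentum, rng=rng, steps=steps)
    except FloatingPointError as err:
        raise FloatingPointError(
            f"client {client.client_id}, round {global_model.round + 1}: {err}"
        ) from err
    return net.params, loss


def aggregate(
    global_model: GlobalModel,
    updates: Sequence[Tuple[Optional[PruningMask], Dict[str, np.ndarray], int, float]],
) -> GlobalModel:
    """Scaling-based weighted average of overlapping submodel parameters.

    ``updates`` holds ``(mask, sub_params, n_samples, pruning_rate)`` per
    client.  For each scalar coordinate the new value is the
    ``w_k = n_k * (1 + rate_k)``-weighted mean over the clients whose mask
    retains it; unretained coordinates keep the previous global value.
    Weights are normalized per coordinate before summation, so a coordinate
    held by a single client takes exactly that client's value.
    """
    if not updates:
        raise ValueError("aggregate requires at least one client update")
    plan = build_plan(global_model.spec)
    schema = param_schema(plan)

    resolved = []
    for mask, sub_params, n_samples, rate in updates:
        mask_dict = mask.as_dict() if isinstance(mask, PruningMask) else mask
        w = float(n_samples) * (1.0 + float(rate))
        if w <= 0:
            raise ValueError("client weight must be positive")
        resolved.append((mask_dict, sub_params, w))

    new_params: Dict[str, np.ndarray] = {}
    for e in schema:
        old = global_model.params[e.key]
        if old.shape != e.shape:
            raise ValueError(f"global parameter {e.key} has inconsistent shape")
        den = np.zeros(e.shape)
        coords = []
        for mask_dict, sub_params, w in resolved:
            index = [np.arange(s, dtype=np.intp) for s in e.shape]
            for axis, ref in e.axis_refs.items():
                index[axis] = resolve_indices(ref, plan.groups, mask_dict)
            ix = np.ix_(*index) if old.ndim > 1 else (index[0],)
            theta = sub_params[e.key]
            want = tuple(len(i) for i in index)
            if theta.shape != want:
                raise ValueError(
                    f"update for {e.key}: shape {theta.shape}, mask implies {want}")
            den[ix] += w
            coords.append((ix, theta, w))
        acc = np.zeros(e.shape)
        for ix, theta, w in coords:
            acc[ix] += theta * (w / den[ix])
        new_params[e.key] = np.where(den > 0, acc, old)
    return GlobalModel(spec=global_model.spec, params=new_params,
                       round=global_model.round + 1)


def client_similarity(importances: Sequence[FilterImportance]) -> np.ndarray:
    """Pairwise cosine similarity of concatenated, per-group-normalized scores."""
    if not importances:
        raise ValueError("no importance vectors")
    vecs = np.stack([imp.concat(normalize=True) for imp in importances])
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    unit = vecs / norms
    sim = np.clip(unit @ unit.T, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def _single_linkage_groups(sim: np.ndarray, tau: float) -> List[List[int]]:
    k = sim.shape[0]
    parent = list(range(k))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(k):
        for j in range(i + 1, k):
            if sim[i, j] >= tau:
                parent[find(i)] = find(j)
    groups: Dict[int, List[int]] = {}
    for i in range(k):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def tune_submodels(
    spec: ModelSpec,
    masks: Sequence[PruningMask],
    importances: Sequence[FilterImportance],
    similarity: np.ndarray,
    budgets: Sequence[ResourceBudget],
    tau: float,
    n_samples: Optional[Sequence[int]] = None,
) -> List[PruningMask]:
    """Server-side mask adjustment by client similarity.

    Clients whose pairwise similarity reaches ``tau`` (single linkage) share
    a sample-count-weighted mean importance ranking; each member re-selects
    its retained indices from that shared ranking at its own retained counts,
    which makes similar clients' masks nested.  An adjustment that would
    break a client's budget falls back to that client's original mask.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must be in [0, 1]")
    k = len(masks)
    weights = np.asarray(n_samples if n_samples is not None else [1.0] * k, dtype=float)
    adjusted = list(masks)
    for group in _single_linkage_groups(np.asarray(similarity), tau):
        if len(group) < 2:
            continue
        w = weights[group] / weights[group].sum()
        shared = FilterImportance({
            g: sum(wi * importances[m].scores[g] for wi, m in zip(w, group))
            for g in importances[group[0]].scores
        })
        for m in group:
            rate = masks[m].nominal_rate
            new_mask = make_mask(spec, shared, rate)
            budget = budgets[m] if m < len(budgets) else ResourceBudget()
            if budget.satisfied_by(count_costs(spec, new_mask.as_dict())):
                adjusted[m] = new_mask
            else:
                warnings.warn(
                    f"tuned mask for client {m} violates its budget; keeping "
                    "the original mask", stacklevel=2)
    return adjusted


def _evaluate_global(model: GlobalModel, test: Tuple[np.ndarray, np.ndarray],
                     eval_batch: int) -> Tuple[float, float, float]:
    net = Network(model.spec, model.params)
    X, y = test
    preds = predict(net, X, batch_size=eval_batch)
    cm = confusion(y, preds, model.spec.num_classes)
    return cm_accuracy(cm), cm_precision(cm), cm_recall(cm)


def run_federated(
    spec: ModelSpec,
    init_params: Dict[str, np.ndarray],
    shards: Sequence[Tuple[np.ndarray, np.ndarray]],
    test: Tuple[np.ndarray, np.ndarray],
    config: FederatedConfig,
    budgets: Optional[Sequence[ResourceBudget]] = None,
) -> Tuple[GlobalModel, List[RoundLog]]:
    """Execute the full round loop; returns the global model and round logs."""
    if not shards:
        raise ValueError("at least one client shard is required")
    if budgets is None:
        budgets = [ResourceBudget() for _ in shards]
    clients = [
        ClientState(client_id=i, data=shard, budget=budget)
        for i, (shard, budget) in enumerate(zip(shards, budgets))
    ]
    for c in clients:
        if c.n_samples == 0:
            raise ValueError(f"client {c.client_id} has an empty shard")
        c.pruning_rate = pruning_rate_for_budget(spec, c.budget)

    model = GlobalModel(spec=spec, params={k: v.copy() for k, v in init_params.items()})
    logs: List[RoundLog] = []
    for r in range(1, config.rounds + 1):
        refresh = (r == 1) or ((r - 1) % config.refresh_period == 0)
        if refresh:
            for c in clients:
                c.importance = learn_importance(
                    spec, model.params, c.data,
                    epochs=config.importance_epochs,
                    rng_seed=int(_round_rng(config.seed, r, c.client_id, 1)
                                 .integers(0, 2**31 - 1)),
                    l1_lambda=config.l1_lambda,
                    gate_lr=config.gate_lr,
                    batch_size=config.batch_size,
                )
                _, _, c.mask = prune(spec, model.params, c.importance, c.pruning_rate)

        updates = []
        losses = []
        for c in clients:
            sub_params, loss = local_update(
                c, model, epochs=config.local_epochs, lr=config.round_lr(r),
                rng_seed=_round_rng(config.seed, r, c.client_id, 0),
                batch_size=config.batch_size, momentum=config.momentum,
                steps=config.local_steps,
            )
            c.sub_params = sub_params
            losses.append(loss)
            updates.append((c.mask, sub_params, c.n_samples, c.mask.pruning_rate))
        model = aggregate(model, updates)

        sim = client_similarity([c.importance for c in clients])
        tuned = tune_submodels(
            spec, [c.mask for c in clients], [c.importance for c in clients],
            sim, [c.budget for c in clients], config.tau,
            n_samples=[c.n_samples for c in clients],
        )
        for c, m in zip(clients, tuned):
            c.mask = m

        acc, prec, rec = _evaluate_global(model, test, config.eval_batch)
        logs.append(RoundLog(
            round=r,
            client_rates=[c.mask.pruning_rate for c in clients],
            client_losses=losses,
            client_samples=[c.n_samples for c in clients],
            accuracy=acc, precision=prec, recall=rec,
            similarity=sim.tolist(),
        ))
    return model, logs


def train_centralized(
    spec: ModelSpec,
    init_params: Dict[str, np.ndarray],
    train: Tuple[np.ndarray, np.ndarray],
    test: Tuple[np.ndarray, np.ndarray],
    config: FederatedConfig,
) -> Tuple[GlobalModel, List[RoundLog]]:
    """Single-site baseline under the same schedule as one federated client.

    Each "round" is ``local_epochs`` epochs of mini-batch SGD with the same
    seeded batching as federated client 0, so a 1-client, unpruned federation
    reproduces this baseline exactly.
    """
    model = GlobalModel(spec=spec, params={k: v.copy() for k, v in init_params.items()})
    X, y = train
    logs: List[RoundLog] = []
    for r in range(1, config.rounds + 1):
        net = Network(spec, model.params)
        loss = train_sgd(net, X, y, epochs=config.local_epochs, lr=config.round_lr(r),
                         batch_size=config.batch_size, momentum=config.momentum,
                         rng=_round_rng(config.seed, r, 0, 0), steps=config.local_steps)
        model = GlobalModel(spec=spec, params=net.params, round=r)
        acc, prec, rec = _evaluate_global(model, test, config.eval_batch)
        logs.append(RoundLog(
            round=r, client_rates=[0.0], client_losses=[loss],
            client_samples=[len(X)], accuracy=acc, precision=prec, recall=rec,
            similarity=[[1.0]],
        ))
    return model, logs
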