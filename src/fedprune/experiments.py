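"""Reusable desk-scale experiment definitions.

The standard benchmark is a 10-class synthetic day-age task: 200 images per
class at 32×32×3, evenly spaced labels, stratified 7:3 split.  The federated
runs use the lightened ``alexnet_s`` backbone at width 0.5 — the
configuration a resource-poor edge client would actually deploy — trained
for 5 rounds of 16 local optimizer steps per client (SGD, lr 0.2 decayed
×0.6 per round, momentum 0.9, batch 48).  Local work is measured in steps,
not epochs: every participating device contributes a fixed amount of
computation per round, so adding clients adds training effort, as it would
in a real edge deployment.  These sizes keep a full client-count sweep
tractable on a single CPU while leaving the learning dynamics non-trivial.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .backbones import build_backbone, lighten
from .federation import FederatedConfig, run_federated, train_centralized
from .graph import init_params
from .ir import ModelSpec
from .synthetic import (
    SplitSpec,
    generate_dataset,
    partition_clients,
    split_train_test,
    stack,
    uniform_class_specs,
)

__all__ = [
    "benchmark_data",
    "benchmark_model",
    "run_benchmark_federated",
    "run_benchmark_centralized",
]

BENCH_CLASSES = 10
BENCH_PER_CLASS = 200
BENCH_IMAGE = (32, 32, 3)


def benchmark_data(
    seed: int,
    client_ratios: Sequence[float] = (1.0,),
    n_classes: int = BENCH_CLASSES,
    per_class: int = BENCH_PER_CLASS,
) -> Tuple[List[Tuple[np.ndarray, np.ndarray]], Tuple[np.ndarray, np.ndarray]]:
    """Per-client training shards and the shared test set for the benchmark."""
    samples = generate_dataset(uniform_class_specs(n_classes, per_class),
                               image_size=BENCH_IMAGE, rng_seed=seed)
    split = SplitSpec(train_fraction=0.7, client_ratios=tuple(client_ratios),
                      rng_seed=seed)
    train, test = split_train_test(samples, split)
    _, _, label_map = stack(train)
    shards = [
        stack(part, label_map)[:2]
        for part in partition_clients(train, split)
    ]
    X_test, y_test, _ = stack(test, label_map)
    return shards, (X_test, y_test)


def benchmark_model(
    num_classes: int = BENCH_CLASSES,
    lightweight: bool = True,
    name: str = "alexnet_s",
    width: float = 0.5,
) -> ModelSpec:
    spec = build_backbone(name, num_classes, width_multiplier=width,
                          input_size=BENCH_IMAGE)
    return lighten(spec) if lightweight else spec


def _config(seed: int, **overrides) -> FederatedConfig:
    cfg = FederatedConfig(seed=seed)
    return replace(cfg, **overrides)


def run_benchmark_federated(
    seed: int,
    client_ratios: Sequence[float],
    lightweight: bool = True,
    model_name: str = "alexnet_s",
    **config_overrides,
) -> Dict[str, object]:
    """One federated benchmark run; returns final metrics and logs."""
    shards, test = benchmark_data(seed, client_ratios)
    spec = benchmark_model(lightweight=lightweight, name=model_name)
    params = init_params(spec, rng_seed=seed + 10_000)
    model, logs = run_federated(spec, params, shards, test,
                                _config(seed, **config_overrides))
    final = logs[-1]
    return {
        "accuracy": final.accuracy,
        "precision": final.precision,
        "recall": final.recall,
        "logs": logs,
        "model": model,
    }


def run_benchmark_centralized(
    seed: int,
    lightweight: bool,
    model_name: str = "alexnet_s",
    **config_overrides,
) -> Dict[str, object]:
    """Single-site baseline on the same benchmark data and schedule."""
    shards, test = benchmark_data(seed, (1.0,))
    spec = benchmark_model(lightweight=lightweight, name=model_name)
    params = init_params(spec, rng_seed=seed + 10_000)
    model, logs = train_centralized(spec, params, shards[0], test,
                                    _config(seed, **config_overrides))
    final = logs[-1]
    return {
        "accuracy": final.accuracy,
        "precision": final.precision,
        "recall": final.recall,
        "logs": logs,
        "model": model,
    }
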