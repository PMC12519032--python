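"""Simulated horizontal federated training with FedAvg aggregation.

Every round the server broadcasts the global weight vector, each client
trains ``local_epochs`` passes on its own partition, and the server replaces
the global weights with the sample-count-weighted average of the client
vectors.  All clients participate every round; client-side optimizer moments
and random streams persist across rounds.

The degenerate case is the keystone of the whole benchmark: with one node
holding all the data, R rounds of one local epoch are bit-identical to R
centralized epochs under the same seed, so every federated-vs-centralized
difference measured downstream is attributable to the data split and the
averaging, never to the harness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .fixtures import ClinicalTable
from .models import GeneratorState, get_weights, set_weights, train
from .partition import PartitionPlan
from .preprocess import Transformer

__all__ = ["FedConfig", "fedavg", "run_federation", "client_seed"]


@dataclass(frozen=True)
class FedConfig:
    N: int
    rounds: int = 500
    local_epochs: int = 1
    aggregation: str = "fedavg"
    seed: int = 0

    def __post_init__(self):
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if self.aggregation != "fedavg":
            raise ValueError(f"unsupported aggregation {self.aggregation!r}")


def fedavg(weight_sets: Sequence[np.ndarray], counts: Sequence[int]) -> np.ndarray:
    """Sample-count-weighted elementwise average: sum_i n_i w_i / sum_i n_i."""
    weight_sets = [np.asarray(w, dtype=np.float64) for w in weight_sets]
    if len(weight_sets) != len(counts) or not weight_sets:
        raise ValueError("need one weight vector per count")
    length = weight_sets[0].size
    if any(w.size != length for w in weight_sets):
        raise ValueError("weight vectors have mismatched lengths")
    counts = np.asarray(counts, dtype=np.float64)
    if (counts <= 0).any():
        raise ValueError("sample counts must be positive")
    stacked = np.stack(weight_sets)
    # normalize first so a single client (fraction exactly 1.0) averages to
    # its own weights bitwise
    frac = counts / counts.sum()
    return (frac[:, None] * stacked).sum(axis=0)


def client_seed(base_seed: int, node: int) -> int:
    """Per-client seed; node 0 reuses the base seed so that a single-node
    federation consumes exactly the centralized random stream."""
    if node == 0:
        return base_seed
    return int((base_seed + 0x9E3779B1 * node) % (2 ** 31))


def run_federation(
    model_factory: Callable[[int], GeneratorState],
    table: ClinicalTable,
    plan: PartitionPlan,
    tr: Transformer,
    fed: FedConfig,
) -> GeneratorState:
    """FedAvg loop over the plan's client partitions.

    ``model_factory(seed)`` must build a fresh state (the transformer inside
    it must be the one fitted on the FULL table).  Returns the final global
    state, fully deterministic given the config seed.
    """
    if plan.N != fed.N:
        raise ValueError("plan node count does not match FedConfig.N")
    if plan.n_total != len(table):
        raise ValueError("plan does not cover the table")
    clients = [model_factory(client_seed(fed.seed, i)) for i in range(fed.N)]
    locals_ = [table.subset(idx) for idx in plan.assignments]
    counts = plan.sizes
    server = model_factory(client_seed(fed.seed, 0))
    global_w = get_weights(server)
    for _ in range(fed.rounds):
        client_w = []
        for st, data in zip(clients, locals_):
            set_weights(st, global_w)
            train(st, data, tr, epochs=fed.local_epochs)
            client_w.append(get_weights(st))
        global_w = fedavg(client_w, counts)
    set_weights(server, global_w)
    server.trained = fed.rounds > 0
    # expose the pooled conditional frequencies of the full table for sampling
    if clients and clients[0].trained:
        from .models import _CondSampler

        server.cond_freqs = _CondSampler(table, tr).freqs
    return server
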