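"""Client partitioning for the three federated data-distribution scenarios.

* ``B`` (balanced): rows split uniformly at random into near-equal nodes.
* ``IB`` (imbalanced): N-1 minority nodes each get a small random fraction
  (default 5%) of the rows; the last node keeps the remainder.
* ``IB_non_iid``: rows are binned by quantiles of a continuous conditioning
  column (age), and within each bin a Dirichlet(alpha) draw sets the
  per-node allocation — the standard label-skew recipe generalized to a
  continuous covariate.  Small alpha concentrates bins on few nodes; as
  alpha grows every node approaches the global age composition.

Plans are computed before any training and are serializable, so a run's
exact client membership is traceable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fixtures import CONTINUOUS, ClinicalTable

__all__ = [
    "PartitionPlan",
    "partition_balanced",
    "partition_imbalanced",
    "partition_dirichlet_noniid",
]

PAPER_NODE_COUNTS = (3, 5, 7, 10)


@dataclass
class PartitionPlan:
    scenario: str
    N: int
    assignments: list[np.ndarray]
    seed: int
    alpha: float | None = None
    minority_frac: float | None = None

    def __post_init__(self):
        self.assignments = [np.asarray(a, dtype=int) for a in self.assignments]
        all_idx = np.concatenate(self.assignments)
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("assignments overlap")
        if any(len(a) == 0 for a in self.assignments):
            raise ValueError("empty client partition")
        if len(self.assignments) != self.N:
            raise ValueError("assignment count does not match N")

    @property
    def sizes(self) -> list[int]:
        return [len(a) for a in self.assignments]

    @property
    def n_total(self) -> int:
        return sum(self.sizes)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "scenario": self.scenario, "N": self.N, "seed": self.seed,
            "alpha": self.alpha, "minority_frac": self.minority_frac,
            "assignments": [a.tolist() for a in self.assignments]}))

    @classmethod
    def from_json(cls, path: str | Path) -> "PartitionPlan":
        d = json.loads(Path(path).read_text())
        return cls(d["scenario"], d["N"], [np.asarray(a) for a in d["assignments"]],
                   d["seed"], d.get("alpha"), d.get("minority_frac"))


def _warn_node_count(N: int) -> None:
    if N not in PAPER_NODE_COUNTS:
        warnings.warn(
            f"node count {N} is outside the study grid {PAPER_NODE_COUNTS}",
            stacklevel=3)


def partition_balanced(n: int, N: int, seed: int) -> PartitionPlan:
    """Uniform random split into N nodes of size floor(n/N), the n mod N
    leftover rows going one each to the first nodes."""
    if N > n:
        raise ValueError(f"cannot split {n} rows across {N} nodes")
    _warn_node_count(N)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base, rem = divmod(n, N)
    sizes = [base + (1 if i < rem else 0) for i in range(N)]
    cuts = np.cumsum([0] + sizes)
    parts = [perm[cuts[i]:cuts[i + 1]] for i in range(N)]
    return PartitionPlan("B", N, parts, seed)


def partition_imbalanced(n: int, N: int, frac: float = 0.05, seed: int = 0) -> PartitionPlan:
    """N-1 minority nodes of round(frac*n) random rows each; the last node
    receives everything left over."""
    if (N - 1) * frac >= 1.0:
        raise ValueError(f"(N-1)*frac = {(N - 1) * frac} leaves no remainder node")
    _warn_node_count(N)
    m = round(frac * n)
    if m < 1:
        raise ValueError("minority fraction yields empty nodes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    parts = [perm[i * m:(i + 1) * m] for i in range(N - 1)]
    parts.append(perm[(N - 1) * m:])
    return PartitionPlan("IB", N, parts, seed, minority_frac=frac)


def _largest_remainder(props: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` items proportional to ``props``."""
    raw = props * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def partition_dirichlet_noniid(
    table: ClinicalTable,
    cond_col: str | None = None,
    N: int = 3,
    alpha: float = 10.0,
    n_bins: int | None = None,
    seed: int = 0,
) -> PartitionPlan:
    """Age-skewed non-IID split.

    Rows are cut into ``n_bins`` quantile strata of ``cond_col`` (default:
    the schema's conditioning column, with N bins); a Dirichlet(alpha)
    vector per stratum sets how that stratum spreads across nodes.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if cond_col is None:
        cond_col = table.schema.conditioning_column
    spec = table.schema.column(cond_col)
    if spec.kind != CONTINUOUS:
        raise ValueError(f"conditioning column {cond_col!r} must be continuous")
    _warn_node_count(N)
    if n_bins is None:
        n_bins = N
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = table.df[cond_col].to_numpy(float)
    n = len(values)
    if N > n:
        raise ValueError(f"cannot split {n} rows across {N} nodes")
    n_distinct = len(np.unique(values))
    if n_distinct < n_bins:
        warnings.warn(
            f"only {n_distinct} distinct {cond_col!r} values; reducing bins",
            stacklevel=2)
        n_bins = max(2, n_distinct)

    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    strata = np.searchsorted(edges, values, side="right")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[] for _ in range(N)]
    for b in range(n_bins):
        rows = np.flatnonzero(strata == b)
        if len(rows) == 0:
            continue
        rows = rng.permutation(rows)
        props = rng.dirichlet(np.full(N, alpha))
        counts = _largest_remainder(props, len(rows))
        pos = 0
        for i in range(N):
            parts[i].extend(rows[pos:pos + counts[i]].tolist())
            pos += counts[i]
    # empty-node repair: move one row from the largest node
    for i in range(N):
        while len(parts[i]) == 0:
            donor = max(range(N), key=lambda j: len(parts[j]))
            parts[i].append(parts[donor].pop())
    return PartitionPlan("IB_non_iid", N, [np.asarray(p) for p in parts], seed, alpha=alpha)
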