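"""Privacy attacks against a synthetic table, reported as excess-over-baseline risk.

Four adversaries are simulated: membership inference (was this record used
for training?), attribute inference (recover a hidden column from the rest),
linkability (match two disjoint attribute views of a person through the
synthetic data) and multivariate singling out (build an all-attribute
predicate that isolates exactly one real record).

Every attack reports a success rate, the success rate of a naive baseline
attacker with no access to the real/synthetic relation, and the normalized
excess risk max(0, (success - baseline) / (1 - baseline)) in [0, 1] — so a
generator that leaks nothing scores ~0 even when the baseline is easy.

Record similarity uses the Gower distance: the mean over columns of the
range-normalized absolute difference (numeric) or the mismatch indicator
(categorical).  Numeric ranges are taken from the reference table's observed
min/max; a zero-range column contributes 0 when equal, 1 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

from .fixtures import CATEGORICAL, CONTINUOUS, ClinicalTable

__all__ = [
    "PrivacyConfig",
    "AttackResult",
    "gower_distance",
    "gower_matrix",
    "mia_risk",
    "aia_risk",
    "linkability_risk",
    "singling_out_risk",
]


@dataclass(frozen=True)
class PrivacyConfig:
    gower_threshold: float = 0.05
    aia_tolerance: float = 0.05
    link_k: int = 1
    n_attacks: int = 500
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.gower_threshold < 1 and 0 < self.aia_tolerance < 1):
            raise ValueError("thresholds must lie in (0, 1)")


@dataclass
class AttackResult:
    success_rate: float
    baseline_rate: float
    per_variable: dict[str, float] = field(default_factory=dict)

    @property
    def risk(self) -> float:
        return _excess_risk(self.success_rate, self.baseline_rate)


def _excess_risk(success: float, baseline: float) -> float:
    if baseline >= 1.0:
        return 0.0
    return float(np.clip((success - baseline) / (1.0 - baseline), 0.0, 1.0))


# --------------------------------------------------------------------------
# Gower distance
# --------------------------------------------------------------------------


def _column_ranges(table: ClinicalTable) -> dict[str, float]:
    out = {}
    for c in table.schema.columns:
        if c.kind == CONTINUOUS:
            col = table.df[c.name].to_numpy(float)
            out[c.name] = float(col.max() - col.min())
    return out


def gower_distance(a, b, schema, ranges: dict[str, float] | None = None) -> float:
    """Gower distance between two records (mappings/Series of column values)."""
    if ranges is None:
        ranges = {c.name: c.range[1] - c.range[0]
                  for c in schema.columns if c.kind == CONTINUOUS}
    parts = []
    for c in schema.columns:
        va, vb = a[c.name], b[c.name]
        if c.kind == CONTINUOUS:
            r = ranges[c.name]
            if r <= 0:
                parts.append(0.0 if va == vb else 1.0)
            else:
                parts.append(min(abs(va - vb) / r, 1.0))
        else:
            parts.append(0.0 if va == vb else 1.0)
    return float(np.mean(parts))


def _column_distance_stack(
    A: ClinicalTable, B: ClinicalTable, ranges: dict[str, float]
) -> np.ndarray:
    """Per-column Gower contributions, shape (p, len(A), len(B)), float32."""
    blocks = []
    for c in A.schema.columns:
        va = A.df[c.name].to_numpy()
        vb = B.df[c.name].to_numpy()
        if c.kind == CONTINUOUS:
            r = ranges[c.name]
            if r <= 0:
                d = (va[:, None] != vb[None, :]).astype(np.float32)
            else:
                d = np.minimum(
                    np.abs(va[:, None] - vb[None, :]) / r, 1.0).astype(np.float32)
        else:
            d = (va[:, None] != vb[None, :]).astype(np.float32)
        blocks.append(d)
    return np.stack(blocks)


def gower_matrix(A: ClinicalTable, B: ClinicalTable,
                 ranges: dict[str, float] | None = None) -> np.ndarray:
    """Pairwise Gower distances, shape (len(A), len(B))."""
    if ranges is None:
        ranges = _column_ranges(A)
    stack = _column_distance_stack(A, B, ranges)
    return stack.mean(axis=0)


# --------------------------------------------------------------------------
# Membership inference
# --------------------------------------------------------------------------


def mia_risk(
    train: ClinicalTable,
    control: ClinicalTable,
    syn: ClinicalTable,
    cfg: PrivacyConfig = PrivacyConfig(),
) -> AttackResult:
    """Claim membership when the nearest synthetic neighbour sits within the
    Gower threshold; the control set (same population, unseen by the model)
    calibrates the baseline claim rate."""
    if len(syn) == 0:
        raise ValueError("empty synthetic table")
    ranges = _column_ranges(train)
    d_train = gower_matrix(train, syn, ranges).min(axis=1)
    d_control = gower_matrix(control, syn, ranges).min(axis=1)
    return AttackResult(
        success_rate=float((d_train <= cfg.gower_threshold).mean()),
        baseline_rate=float((d_control <= cfg.gower_threshold).mean()),
    )


# --------------------------------------------------------------------------
# Attribute inference
# --------------------------------------------------------------------------


def aia_risk(
    real: ClinicalTable,
    syn: ClinicalTable,
    cfg: PrivacyConfig = PrivacyConfig(),
) -> AttackResult:
    """Each column in turn is the secret: the attacker reads it off the real
    record's nearest synthetic neighbour over the remaining columns.  The
    baseline attacker predicts by drawing from the synthetic marginal.
    Numeric success means landing within tolerance * range of the truth;
    categorical requires an exact match.  Overall rates are column means."""
    schema = real.schema
    p = len(schema.columns)
    if p < 2:
        raise ValueError("attribute inference needs at least 2 columns")
    if len(real) == 0 or len(syn) == 0:
        raise ValueError("empty tables")
    rng = np.random.default_rng(cfg.seed)
    ranges = _column_ranges(real)
    stack = _column_distance_stack(real, syn, ranges)
    total = stack.sum(axis=0)
    per_risk, succ_rates, base_rates = {}, [], []
    for ci, c in enumerate(schema.columns):
        d = (total - stack[ci]) / (p - 1)
        nn = d.argmin(axis=1)
        truth = real.df[c.name].to_numpy()
        pred = syn.df[c.name].to_numpy()[nn]
        base_pred = rng.choice(syn.df[c.name].to_numpy(), size=len(real), replace=True)
        if c.kind == CONTINUOUS:
            tol = cfg.aia_tolerance * max(ranges[c.name], 1e-12)
            hit = np.abs(pred - truth) <= tol
            base_hit = np.abs(base_pred - truth) <= tol
        else:
            hit = pred == truth
            base_hit = base_pred == truth
        s, b = float(hit.mean()), float(base_hit.mean())
        succ_rates.append(s)
        base_rates.append(b)
        per_risk[c.name] = _excess_risk(s, b)
    return AttackResult(float(np.mean(succ_rates)), float(np.mean(base_rates)), per_risk)


# --------------------------------------------------------------------------
# Linkability
# --------------------------------------------------------------------------


def linkability_risk(
    real: ClinicalTable,
    syn: ClinicalTable,
    colsA: list[str] | None = None,
    colsB: list[str] | None = None,
    cfg: PrivacyConfig = PrivacyConfig(),
) -> AttackResult:
    """Two disjoint attribute views of each real record are matched to their
    nearest synthetic neighbours; linkage succeeds when the neighbour sets
    intersect.  Baseline: the exact probability that two uniformly random
    k-subsets of the synthetic rows intersect."""
    names = real.schema.names
    if colsA is None and colsB is None:
        colsA, colsB = names[: len(names) // 2], names[len(names) // 2:]
    if set(colsA) & set(colsB):
        raise ValueError("colsA and colsB must be disjoint")
    k = cfg.link_k
    n_syn = len(syn)
    if k >= n_syn:
        raise ValueError("link_k must be smaller than the synthetic table")
    ranges = _column_ranges(real)
    stack = _column_distance_stack(real, syn, ranges)
    idx = {nm: i for i, nm in enumerate(names)}
    dA = stack[[idx[c] for c in colsA]].mean(axis=0)
    dB = stack[[idx[c] for c in colsB]].mean(axis=0)
    nnA = np.argpartition(dA, k - 1, axis=1)[:, :k]
    nnB = np.argpartition(dB, k - 1, axis=1)[:, :k]
    hits = np.array([bool(set(a) & set(b)) for a, b in zip(nnA, nnB)])
    baseline = 1.0 - comb(n_syn - k, k) / comb(n_syn, k)
    return AttackResult(float(hits.mean()), float(baseline))


# --------------------------------------------------------------------------
# Singling out
# --------------------------------------------------------------------------


def _predicate_match_counts(
    source: ClinicalTable, real: ClinicalTable, rows: np.ndarray,
    tol_frac: float, ranges: dict[str, float],
) -> np.ndarray:
    """For each source row, how many real records satisfy the all-attribute
    predicate read off it (categorical equality, numeric within +-tol*range)."""
    schema = real.schema
    counts = np.zeros(len(rows), dtype=int)
    real_cols = {c.name: real.df[c.name].to_numpy() for c in schema.columns}
    for out_i, i in enumerate(rows):
        mask = np.ones(len(real), dtype=bool)
        for c in schema.columns:
            v = source.df[c.name].iloc[i]
            if c.kind == CONTINUOUS:
                tol = tol_frac * max(ranges[c.name], 1e-12)
                mask &= np.abs(real_cols[c.name] - v) <= tol
            else:
                mask &= real_cols[c.name] == v
            if not mask.any():
                break
        counts[out_i] = int(mask.sum())
    return counts


def singling_out_risk(
    real: ClinicalTable,
    syn: ClinicalTable,
    cfg: PrivacyConfig = PrivacyConfig(),
    baseline_table: ClinicalTable | None = None,
) -> AttackResult:
    """Multivariate singling out: predicates conjoin conditions on ALL
    attributes of a sampled synthetic record; success is matching EXACTLY ONE
    real record.  The baseline builds predicates the same way from an
    independent draw of the same schema (generated on the fly when not
    supplied)."""
    if cfg.n_attacks < 1:
        raise ValueError("n_attacks must be >= 1")
    if len(real) == 0 or len(syn) == 0:
        raise ValueError("empty tables")
    rng = np.random.default_rng(cfg.seed)
    ranges = _column_ranges(real)
    if baseline_table is None:
        from .fixtures import generate_fixture

        baseline_table = generate_fixture(
            real.schema, len(syn), seed=int(rng.integers(2 ** 31)))
    rows_syn = rng.integers(0, len(syn), size=cfg.n_attacks)
    rows_base = rng.integers(0, len(baseline_table), size=cfg.n_attacks)
    c_syn = _predicate_match_counts(syn, real, rows_syn, cfg.aia_tolerance, ranges)
    c_base = _predicate_match_counts(
        baseline_table, real, rows_base, cfg.aia_tolerance, ranges)
    return AttackResult(float((c_syn == 1).mean()), float((c_base == 1).mean()))
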