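"""Global encoding of a mixed table into the models' continuous representation.

Continuous columns get mode-specific normalization: a Gaussian mixture with up
to ``max_modes`` components is fitted per column, a mode k* is selected per
cell (by responsibility), and the cell is represented as a normalized scalar
alpha = (v - mu_k*) / (4 sigma_k*), clipped to [-1, 1], next to a one-hot mode
indicator.  Categorical columns become plain one-hots over their label codes.

The transformer is fitted ONCE on the full table before any client
partitioning and the same object is shared by every federated client, so all
nodes encode into an identical layout and no client ever meets an unseen
label.  ``inverse_transform`` is the exact algebraic inverse up to clipping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .fixtures import CATEGORICAL, CONTINUOUS, ClinicalTable, TableSchema

__all__ = ["ColumnTransform", "Transformer", "EncodedTable", "fit_transformer",
           "transform", "inverse_transform"]

_WEIGHT_PRUNE = 0.005
_FLOOR_SCALE = 1e-6


@dataclass
class ColumnTransform:
    """Fitted encoding state for one column."""

    name: str
    kind: str
    # continuous: mixture parameters (arrays of length K)
    weights: np.ndarray | None = None
    means: np.ndarray | None = None
    scales: np.ndarray | None = None
    # categorical: ordered labels; code i -> one-hot position i
    labels: list[str] | None = None

    @property
    def width(self) -> int:
        if self.kind == CONTINUOUS:
            return 1 + len(self.means)
        return len(self.labels)

    def to_dict(self) -> dict:
        d = {"name": self.name, "kind": self.kind}
        if self.kind == CONTINUOUS:
            d.update(weights=self.weights.tolist(), means=self.means.tolist(),
                     scales=self.scales.tolist())
        else:
            d["labels"] = self.labels
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnTransform":
        if d["kind"] == CONTINUOUS:
            return cls(d["name"], CONTINUOUS, np.asarray(d["weights"]),
                       np.asarray(d["means"]), np.asarray(d["scales"]))
        return cls(d["name"], CATEGORICAL, labels=list(d["labels"]))


@dataclass
class Transformer:
    columns: list[ColumnTransform]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.columns]

    @property
    def output_width(self) -> int:
        return sum(c.width for c in self.columns)

    def spans(self) -> list[tuple[int, int]]:
        """Column block boundaries [start, stop) in the encoded layout."""
        out, pos = [], 0
        for c in self.columns:
            out.append((pos, pos + c.width))
            pos += c.width
        return out

    def column(self, name: str) -> ColumnTransform:
        return self.columns[self.names.index(name)]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"columns": [c.to_dict() for c in self.columns]}))

    @classmethod
    def from_json(cls, path: str | Path) -> "Transformer":
        d = json.loads(Path(path).read_text())
        return cls([ColumnTransform.from_dict(c) for c in d["columns"]])


@dataclass
class EncodedTable:
    """Real-valued model representation of a table (n x output_width)."""

    data: np.ndarray
    transformer: Transformer
    schema: TableSchema

    def __len__(self) -> int:
        return self.data.shape[0]


def _fit_continuous(values: np.ndarray, max_modes: int, seed: int) -> tuple:
    if np.ptp(values) < 1e-12:
        # constant column: degenerate single mode with floored scale
        return (np.array([1.0]), np.array([values[0]]), np.array([_FLOOR_SCALE]))
    kmax = min(max_modes, len(np.unique(values)))
    X = values.reshape(-1, 1)
    # EM over 1..kmax components, model order chosen by BIC: a single
    # Gaussian stays one mode, well-separated mixtures keep one per mode
    gm, best = None, np.inf
    for k in range(1, kmax + 1):
        cand = GaussianMixture(n_components=k, covariance_type="diag",
                               random_state=seed, max_iter=200, reg_covar=1e-6)
        cand.fit(X)
        bic = cand.bic(X)
        if bic < best - 1e-9:
            gm, best = cand, bic
    w = gm.weights_.ravel()
    keep = w >= _WEIGHT_PRUNE
    if not keep.any():
        keep = np.array([True] * len(w))
    w = w[keep] / w[keep].sum()
    mu = gm.means_.ravel()[keep]
    sd = np.sqrt(gm.covariances_.ravel()[keep])
    sd = np.maximum(sd, _FLOOR_SCALE)
    order = np.argsort(mu)  # stable documented ordering of modes
    return w[order], mu[order], sd[order]


def fit_transformer(table: ClinicalTable, max_modes: int = 10, seed: int = 0) -> Transformer:
    """Fit the global encoder on the FULL table (before partitioning).

    Mixtures are fitted by expectation-maximization with up to ``max_modes``
    components per continuous column; components with weight < 0.005 are
    pruned and the rest renormalized.
    """
    if len(table) == 0:
        raise ValueError("cannot fit a transformer on an empty table")
    if max_modes < 1:
        raise ValueError("max_modes must be >= 1")
    cols = []
    for spec in table.schema.columns:
        if spec.kind == CONTINUOUS:
            w, mu, sd = _fit_continuous(table.df[spec.name].to_numpy(float), max_modes, seed)
            cols.append(ColumnTransform(spec.name, CONTINUOUS, w, mu, sd))
        else:
            cols.append(ColumnTransform(spec.name, CATEGORICAL, labels=spec.labels))
    return Transformer(cols)


def _responsibilities(v: np.ndarray, ct: ColumnTransform) -> np.ndarray:
    logp = stats.norm.logpdf(v[:, None], ct.means[None, :], ct.scales[None, :])
    logp = logp + np.log(ct.weights[None, :])
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    return p / p.sum(axis=1, keepdims=True)


def transform(
    table: ClinicalTable,
    tr: Transformer,
    seed: int = 0,
    deterministic_modes: bool = False,
) -> EncodedTable:
    """Encode a table.  Mode selection is seeded-random by responsibility
    unless ``deterministic_modes`` (argmax responsibility) is set."""
    if list(table.df.columns) != tr.names:
        raise ValueError("table columns do not match transformer order")
    rng = np.random.default_rng(seed)
    n = len(table)
    blocks = []
    for ct in tr.columns:
        col = table.df[ct.name].to_numpy()
        if ct.kind == CONTINUOUS:
            v = col.astype(float)
            resp = _responsibilities(v, ct)
            if deterministic_modes:
                ks = resp.argmax(axis=1)
            else:
                cum = resp.cumsum(axis=1)
                u = rng.random(n)
                ks = (u[:, None] < cum).argmax(axis=1)
            alpha = (v - ct.means[ks]) / (4.0 * ct.scales[ks])
            alpha = np.clip(alpha, -1.0, 1.0)
            onehot = np.zeros((n, len(ct.means)))
            onehot[np.arange(n), ks] = 1.0
            blocks.append(np.column_stack([alpha, onehot]))
        else:
            codes = col.astype(int)
            bad = (codes < 0) | (codes >= len(ct.labels))
            if bad.any():
                raise ValueError(
                    f"unseen label code {codes[bad][0]} in column {ct.name!r}")
            onehot = np.zeros((n, len(ct.labels)))
            onehot[np.arange(n), codes] = 1.0
            blocks.append(onehot)
    return EncodedTable(np.concatenate(blocks, axis=1), tr, table.schema)


def inverse_transform(enc: EncodedTable | np.ndarray, tr: Transformer,
                      schema: TableSchema | None = None) -> ClinicalTable:
    """Decode model-space rows back to a table.

    Continuous: k* = argmax of the mode block (ties break to the lowest
    index, the NumPy argmax convention; an all-zero block therefore decodes
    via mode 0), v = alpha * 4 sigma_k* + mu_k*, clipped to the column range.
    Categorical: argmax of the one-hot block.
    """
    import pandas as pd

    if isinstance(enc, EncodedTable):
        data, schema = enc.data, enc.schema
    else:
        data = np.asarray(enc, dtype=float)
        if schema is None:
            raise ValueError("schema required when decoding a raw array")
    if data.shape[1] != tr.output_width:
        raise ValueError(
            f"encoded width {data.shape[1]} does not match transformer "
            f"width {tr.output_width}")
    out = {}
    for (start, stop), ct in zip(tr.spans(), tr.columns):
        block = data[:, start:stop]
        if ct.kind == CONTINUOUS:
            alpha = block[:, 0]
            ks = block[:, 1:].argmax(axis=1)
            v = alpha * 4.0 * ct.scales[ks] + ct.means[ks]
            spec = schema.column(ct.name)
            v = np.clip(v, spec.range[0], spec.range[1])
            out[ct.name] = v
        else:
            out[ct.name] = block.argmax(axis=1).astype(int)
    table = ClinicalTable(schema, pd.DataFrame(out, columns=schema.names))
    return table
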