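"""Synthetic mixed-type clinical table emulating an AML patient cohort.

The real study table (1540 records, 12 clinical/demographic/disease features
after dropping genetic-mutation variables) is access-controlled, so every
downstream stage of this package runs on an explicit, documented emulation:
an `age` column suitable for non-IID conditioning, a handful of lab-like
continuous measurements, and label-encoded categorical disease descriptors,
coupled through a Gaussian copula with a fixed rank-correlation target.

Records are drawn by sampling a correlated multivariate normal, pushing each
coordinate through the standard normal CDF, and inverting the column's
marginal (range-truncated for continuous columns, cumulative-probability
cut-points for categorical ones).  Identical ``(schema, n, seed)`` always
yields identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ColumnSpec",
    "TableSchema",
    "ClinicalTable",
    "build_aml_schema",
    "generate_fixture",
]

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

_FAMILIES = {"norm": stats.norm, "lognorm": stats.lognorm}


@dataclass
class ColumnSpec:
    """One column of the table schema.

    For continuous columns ``distribution`` is ``(family, params)`` with
    ``family`` in ``{"norm", "lognorm"}`` and scipy-style params; the marginal
    is truncated to ``range``.  For categorical columns it is
    ``(labels, probabilities)``; values are stored as integer codes into
    ``labels`` (label encoding).
    """

    name: str
    kind: str
    distribution: tuple
    range: tuple[float, float] | None = None
    conditioning: bool = False

    def __post_init__(self):
        if self.kind == CONTINUOUS:
            lo, hi = self.range
            if not lo < hi:
                raise ValueError(f"{self.name}: range min must be < max")
            if self.distribution[0] not in _FAMILIES:
                raise ValueError(f"{self.name}: unknown family {self.distribution[0]}")
        elif self.kind == CATEGORICAL:
            labels, probs = self.distribution
            if len(labels) != len(probs):
                raise ValueError(f"{self.name}: labels/probs length mismatch")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: probabilities must sum to 1")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind}")

    # Marginal inverse CDF on [0, 1] -----------------------------------
    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.kind == CATEGORICAL:
            _, probs = self.distribution
            cuts = np.cumsum(probs)
            return np.searchsorted(cuts, u, side="right").clip(0, len(probs) - 1)
        family, params = self.distribution
        dist = _FAMILIES[family](**params)
        lo, hi = self.range
        a, b = dist.cdf(lo), dist.cdf(hi)
        return dist.ppf(a + u * (b - a))

    def cdf(self, x: np.ndarray) -> np.ndarray:
        """Truncated-marginal CDF (continuous columns only)."""
        family, params = self.distribution
        dist = _FAMILIES[family](**params)
        lo, hi = self.range
        a, b = dist.cdf(lo), dist.cdf(hi)
        return (dist.cdf(x) - a) / (b - a)

    @property
    def n_levels(self) -> int:
        if self.kind != CATEGORICAL:
            raise ValueError(f"{self.name} is continuous")
        return len(self.distribution[0])

    @property
    def labels(self) -> list[str]:
        return list(self.distribution[0])

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "distribution": [self.distribution[0], self.distribution[1]],
            "range": list(self.range) if self.range else None,
            "conditioning": self.conditioning,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnSpec":
        dist = d["distribution"]
        if d["kind"] == CONTINUOUS:
            dist = (dist[0], dict(dist[1]))
        else:
            dist = (list(dist[0]), list(dist[1]))
        rng_ = tuple(d["range"]) if d.get("range") else None
        return cls(d["name"], d["kind"], dist, rng_, d.get("conditioning", False))


@dataclass
class TableSchema:
    columns: list[ColumnSpec]
    n_default: int = 1540
    correlation: np.ndarray = field(default=None)

    def __post_init__(self):
        p = len(self.columns)
        if self.correlation is None:
            self.correlation = np.eye(p)
        self.correlation = np.asarray(self.correlation, dtype=float)
        R = self.correlation
        if R.shape != (p, p):
            raise ValueError("correlation shape must match column count")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semidefinite")
        cond = [c.name for c in self.columns if c.conditioning]
        if len(cond) != 1:
            raise ValueError("exactly one conditioning column required")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.columns]

    @property
    def conditioning_column(self) -> str:
        return next(c.name for c in self.columns if c.conditioning)

    def column(self, name: str) -> ColumnSpec:
        return self.columns[self.names.index(name)]

    def continuous_names(self) -> list[str]:
        return [c.name for c in self.columns if c.kind == CONTINUOUS]

    def categorical_names(self) -> list[str]:
        return [c.name for c in self.columns if c.kind == CATEGORICAL]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def to_dict(self) -> dict:
        return {
            "columns": [c.to_dict() for c in self.columns],
            "n_default": self.n_default,
            "correlation": self.correlation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TableSchema":
        return cls(
            [ColumnSpec.from_dict(c) for c in d["columns"]],
            d["n_default"],
            np.asarray(d["correlation"]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TableSchema":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ClinicalTable:
    """A rectangular mixed-type table plus its schema.

    Continuous cells are floats within the column range; categorical cells
    are integer label codes.  No missing values.
    """

    schema: TableSchema
    df: pd.DataFrame

    def __post_init__(self):
        if list(self.df.columns) != self.schema.names:
            raise ValueError("table columns do not match schema order")

    def validate(self) -> None:
        for c in self.schema.columns:
            col = self.df[c.name]
            if col.isna().any():
                raise ValueError(f"{c.name}: missing cells")
            if c.kind == CONTINUOUS:
                lo, hi = c.range
                if col.min() < lo - 1e-9 or col.max() > hi + 1e-9:
                    raise ValueError(f"{c.name}: value outside range")
            else:
                codes = col.to_numpy()
                if codes.min() < 0 or codes.max() >= c.n_levels:
                    raise ValueError(f"{c.name}: categorical code out of label set")
                if not np.array_equal(codes, codes.astype(int)):
                    raise ValueError(f"{c.name}: non-integer categorical code")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_columns(self) -> int:
        return len(self.schema.columns)

    def subset(self, idx) -> "ClinicalTable":
        return ClinicalTable(self.schema, self.df.iloc[np.asarray(idx)].reset_index(drop=True))

    def to_csv(self, path: str | Path, schema_path: str | Path | None = None) -> None:
        path = Path(path)
        self.df.to_csv(path, index=False)
        if schema_path is None:
            schema_path = path.with_suffix(".schema.json")
        self.schema.to_json(schema_path)

    @classmethod
    def from_csv(cls, path: str | Path, schema_path: str | Path | None = None) -> "ClinicalTable":
        path = Path(path)
        if schema_path is None:
            schema_path = path.with_suffix(".schema.json")
        schema = TableSchema.from_json(schema_path)
        df = pd.read_csv(path)
        for c in schema.categorical_names():
            df[c] = df[c].astype(int)
        return cls(schema, df[schema.names])


# --------------------------------------------------------------------------
# The default 12-column emulation
# --------------------------------------------------------------------------


def build_aml_schema() -> TableSchema:
    """Fixed 12-column emulation of an adult AML clinical table.

    Five continuous columns (age plus four lab-like measurements, two of
    them log-normal as blood counts typically are) and seven label-encoded
    categoricals with 2-5 levels.  The rank-correlation target encodes a few
    clinically plausible couplings: older age with adverse cytogenetic risk
    and secondary disease, high marrow blast burden with high white-cell
    count, anaemia travelling with thrombocytopenia.
    """
    cols = [
        ColumnSpec("age", CONTINUOUS, ("norm", {"loc": 55.0, "scale": 16.0}),
                   (18.0, 90.0), conditioning=True),
        ColumnSpec("wbc", CONTINUOUS, ("lognorm", {"s": 1.3, "scale": 12.0}), (0.3, 400.0)),
        ColumnSpec("hb", CONTINUOUS, ("norm", {"loc": 9.5, "scale": 1.8}), (4.0, 17.0)),
        ColumnSpec("platelets", CONTINUOUS, ("lognorm", {"s": 0.8, "scale": 60.0}), (5.0, 1000.0)),
        ColumnSpec("bm_blasts", CONTINUOUS, ("norm", {"loc": 55.0, "scale": 25.0}), (20.0, 100.0)),
        ColumnSpec("sex", CATEGORICAL, (["male", "female"], [0.54, 0.46])),
        ColumnSpec("ecog", CATEGORICAL, (["0", "1", "2", "3+"], [0.35, 0.40, 0.17, 0.08])),
        ColumnSpec("cyto_risk", CATEGORICAL,
                   (["favorable", "intermediate", "adverse"], [0.20, 0.55, 0.25])),
        ColumnSpec("who_class", CATEGORICAL,
                   (["rec_genetic", "mds_related", "therapy_related", "nos", "other"],
                    [0.33, 0.22, 0.08, 0.30, 0.07])),
        ColumnSpec("secondary_aml", CATEGORICAL, (["no", "yes"], [0.80, 0.20])),
        ColumnSpec("transplant", CATEGORICAL, (["no", "yes"], [0.70, 0.30])),
        ColumnSpec("cr_status", CATEGORICAL,
                   (["cr", "no_cr", "unknown"], [0.55, 0.35, 0.10])),
    ]
    names = [c.name for c in cols]
    R = np.eye(12)

    def set_r(a: str, b: str, r: float) -> None:
        i, j = names.index(a), names.index(b)
        R[i, j] = R[j, i] = r

    set_r("age", "cyto_risk", 0.25)
    set_r("age", "secondary_aml", 0.30)
    set_r("age", "transplant", -0.35)
    set_r("age", "ecog", 0.20)
    set_r("age", "cr_status", 0.15)
    set_r("wbc", "bm_blasts", 0.45)
    set_r("wbc", "who_class", 0.10)
    set_r("hb", "platelets", 0.30)
    set_r("hb", "ecog", -0.15)
    set_r("bm_blasts", "cyto_risk", 0.20)
    set_r("cyto_risk", "cr_status", 0.25)
    set_r("secondary_aml", "who_class", 0.20)
    set_r("cyto_risk", "secondary_aml", 0.15)
    return TableSchema(cols, n_default=1540, correlation=R)


def generate_fixture(schema: TableSchema, n: int, seed: int) -> ClinicalTable:
    """Draw ``n`` records via a Gaussian copula with ``schema.correlation``.

    Deterministic given ``(schema, n, seed)``.  Raises if the correlation
    target is not positive semidefinite.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    R = schema.correlation
    w, V = np.linalg.eigh(R)
    if w.min() < -1e-10:
        raise ValueError("correlation matrix is not positive semidefinite")
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(schema.columns))) @ L.T
    u = stats.norm.cdf(z)
    data = {}
    for j, c in enumerate(schema.columns):
        vals = c.ppf(u[:, j])
        data[c.name] = vals.astype(int) if c.kind == CATEGORICAL else vals
    table = ClinicalTable(schema, pd.DataFrame(data, columns=schema.names))
    table.validate()
    return table
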