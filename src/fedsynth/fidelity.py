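"""Fidelity battery comparing a synthetic table against the real one.

* phik correlation matrices (mixed continuous/categorical pairs) compared via
  cosine similarity of their strict upper triangles;
* the Vendi Score — effective diversity, exp of the Shannon entropy of the
  eigenvalues of the normalized cosine-similarity kernel of the numeric
  columns;
* per-column Hellinger distances and their mean;
* the DD-plot R^2: Mahalanobis-depth agreement of the two multivariate
  samples against the identity line;
* data labeling analysis (DLA): a fixed roster of six standard classifiers
  trained to tell real rows from synthetic ones, the best one (by F1, the
  most restrictive case) reported.

phik follows its original construction: bin both variables, compute the
Pearson chi-square, subtract the (r-1)(c-1) noise pedestal, and invert to
the correlation of a binned bivariate normal whose bin edges match the
observed marginals, via a monotone root-find on rho in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, recall_score, roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .fixtures import CATEGORICAL, CONTINUOUS, ClinicalTable

__all__ = [
    "CorrelationMatrix",
    "DLAResult",
    "phik",
    "phik_matrix",
    "matrix_cosine_similarity",
    "vendi_score",
    "hellinger_distance",
    "mean_hellinger",
    "ddplot_r2",
    "dla",
]

_Z_CLIP = 8.0
_GL_NODES = 24


@dataclass
class CorrelationMatrix:
    values: np.ndarray
    names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names), len(self.names)):
            raise ValueError("matrix shape does not match names")


# --------------------------------------------------------------------------
# phik
# --------------------------------------------------------------------------


def _bin_values(values: np.ndarray, kind: str, n_bins: int) -> np.ndarray:
    if kind == CATEGORICAL:
        codes = values.astype(int)
        _, dense = np.unique(codes, return_inverse=True)
        return dense
    edges = np.unique(np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, values, side="right")


def _bvn_bin_probs(px: np.ndarray, py: np.ndarray, rho: float) -> np.ndarray:
    """Cell probabilities of a standard bivariate normal with correlation
    ``rho``, binned at the edges matching the observed marginals.

    Integrated by Gauss-Legendre over x within each x-bin; the y dimension
    uses the conditional normal CDF in closed form.
    """
    zx = stats.norm.ppf(np.clip(np.cumsum(px), 0, 1))[:-1]
    zy = stats.norm.ppf(np.clip(np.cumsum(py), 0, 1))[:-1]
    ax = np.concatenate([[-_Z_CLIP], np.clip(zx, -_Z_CLIP, _Z_CLIP), [_Z_CLIP]])
    by = np.concatenate([[-_Z_CLIP], np.clip(zy, -_Z_CLIP, _Z_CLIP), [_Z_CLIP]])
    rho = float(np.clip(rho, -0.99999, 0.99999))
    s = np.sqrt(1.0 - rho * rho)
    nodes, weights = np.polynomial.legendre.leggauss(_GL_NODES)
    lo, hi = ax[:-1], ax[1:]
    half = (hi - lo) / 2.0
    mid = (hi + lo) / 2.0
    t = mid[:, None] + half[:, None] * nodes[None, :]          # (rx, g)
    w = half[:, None] * weights[None, :] * stats.norm.pdf(t)   # (rx, g)
    cdf = stats.norm.cdf((by[None, None, :] - rho * t[:, :, None]) / s)  # (rx, g, ry+1)
    seg = cdf[:, :, 1:] - cdf[:, :, :-1]                        # (rx, g, ry)
    probs = (w[:, :, None] * seg).sum(axis=1)                   # (rx, ry)
    probs = np.clip(probs, 0, None)
    tot = probs.sum()
    return probs / tot if tot > 0 else probs


def _expected_chi2(px: np.ndarray, py: np.ndarray, rho: float, n: int) -> float:
    p = _bvn_bin_probs(px, py, rho)
    e = np.outer(px, py)
    mask = e > 0
    return float(n * ((p[mask] - e[mask]) ** 2 / e[mask]).sum())


def phik(
    x: np.ndarray,
    y: np.ndarray,
    kind_x: str = CONTINUOUS,
    kind_y: str = CONTINUOUS,
    n_bins: int = 10,
) -> float:
    """phik coefficient of one variable pair, in [0, 1]."""
    bx = _bin_values(np.asarray(x), kind_x, n_bins)
    by = _bin_values(np.asarray(y), kind_y, n_bins)
    r, c = bx.max() + 1, by.max() + 1
    if r < 2 or c < 2:  # a constant column carries no association
        return 0.0
    n = len(bx)
    obs = np.zeros((r, c))
    np.add.at(obs, (bx, by), 1.0)
    px = obs.sum(axis=1) / n
    py = obs.sum(axis=0) / n
    e = np.outer(px, py) * n
    mask = e > 0
    chi2 = float(((obs[mask] - e[mask]) ** 2 / e[mask]).sum())
    pedestal = (r - 1) * (c - 1)
    chi2_corr = max(0.0, chi2 - pedestal)
    if chi2_corr == 0.0:
        return 0.0
    hi = 0.9999
    if _expected_chi2(px, py, hi, n) <= chi2_corr:
        return 1.0
    rho = optimize.brentq(
        lambda r_: _expected_chi2(px, py, r_, n) - chi2_corr, 0.0, hi, xtol=1e-6)
    return float(rho)


def phik_matrix(table: ClinicalTable, n_bins: int = 10) -> CorrelationMatrix:
    """Pairwise phik over all schema columns; symmetric, unit diagonal."""
    if len(table) < 2:
        raise ValueError("need at least 2 rows")
    cols = table.schema.columns
    p = len(cols)
    out = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            v = phik(
                table.df[cols[i].name].to_numpy(),
                table.df[cols[j].name].to_numpy(),
                cols[i].kind, cols[j].kind, n_bins)
            out[i, j] = out[j, i] = v
    return CorrelationMatrix(out, table.schema.names)


def matrix_cosine_similarity(
    A: CorrelationMatrix | np.ndarray,
    B: CorrelationMatrix | np.ndarray,
    full_matrix: bool = False,
) -> float:
    """1 - d_cos between the two matrices' strict upper triangles (the
    diagonal is identically one and would inflate similarity; pass
    ``full_matrix`` to include it anyway)."""
    a = A.values if isinstance(A, CorrelationMatrix) else np.asarray(A, float)
    b = B.values if isinstance(B, CorrelationMatrix) else np.asarray(B, float)
    if a.shape != b.shape:
        raise ValueError("matrix shapes differ")
    if full_matrix:
        x, y = a.ravel(), b.ravel()
    else:
        iu = np.triu_indices(a.shape[0], k=1)
        x, y = a[iu], b[iu]
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 and ny == 0:
        return 1.0
    if nx == 0 or ny == 0:
        return 0.0
    return float(np.dot(x, y) / (nx * ny))


# --------------------------------------------------------------------------
# Vendi Score
# --------------------------------------------------------------------------


def vendi_score(table: ClinicalTable, standardize: bool = True) -> float:
    """exp(Shannon entropy of the eigenvalues of K/n), K the cosine-similarity
    kernel of the numeric columns (z-scored by default so that no column's
    scale dominates the cosine geometry).  Ranges from 1 to n."""
    num = table.schema.continuous_names()
    if not num:
        raise ValueError("Vendi Score needs at least one continuous column")
    X = table.df[num].to_numpy(float)
    if standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        keep = sd > 1e-12
        if not keep.any():
            # every column constant: all rows identical, diversity is 1
            return 1.0
        X = (X[:, keep] - mu[keep]) / sd[keep]
    norms = np.linalg.norm(X, axis=1)
    ok = norms > 1e-12
    if not ok.all():
        warnings.warn(f"excluding {(~ok).sum()} zero-norm rows from Vendi Score")
        X, norms = X[ok], norms[ok]
    n = X.shape[0]
    U = X / norms[:, None]
    K = U @ U.T
    lam = np.linalg.eigvalsh(K / n)
    if lam.min() < -1e-8:
        raise ValueError("similarity kernel is not positive semidefinite")
    lam = np.clip(lam, 0.0, None)
    lam = lam[lam > 0]
    return float(np.exp(-(lam * np.log(lam)).sum()))


# --------------------------------------------------------------------------
# Hellinger
# --------------------------------------------------------------------------


def hellinger_distance(
    real_col: np.ndarray,
    syn_col: np.ndarray,
    kind: str,
    n_bins: int = 20,
) -> float:
    """sqrt(1 - sum sqrt(p q)); categorical over the label union, continuous
    over equal-width bins spanning the pooled range."""
    real_col, syn_col = np.asarray(real_col), np.asarray(syn_col)
    if len(real_col) == 0 or len(syn_col) == 0:
        raise ValueError("empty column")
    if kind == CATEGORICAL:
        levels = np.union1d(real_col, syn_col)
        p = np.array([(real_col == l).mean() for l in levels])
        q = np.array([(syn_col == l).mean() for l in levels])
    else:
        lo = min(real_col.min(), syn_col.min())
        hi = max(real_col.max(), syn_col.max())
        if hi <= lo:
            hi = lo + 1e-12
        edges = np.linspace(lo, hi, n_bins + 1)
        p = np.histogram(real_col, bins=edges)[0] / len(real_col)
        q = np.histogram(syn_col, bins=edges)[0] / len(syn_col)
    bc = np.sqrt(p * q).sum()
    return float(np.sqrt(max(0.0, 1.0 - bc)))


def mean_hellinger(real: ClinicalTable, syn: ClinicalTable, n_bins: int = 20) -> float:
    """Average Hellinger distance over the schema's columns."""
    vals = [
        hellinger_distance(real.df[c.name].to_numpy(), syn.df[c.name].to_numpy(),
                           c.kind, n_bins)
        for c in real.schema.columns
    ]
    return float(np.mean(vals))


# --------------------------------------------------------------------------
# DD-plot
# --------------------------------------------------------------------------


def _mahalanobis_depth(Z: np.ndarray, S: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    mu = S.mean(axis=0)
    cov = np.cov(S, rowvar=False) + ridge * np.eye(S.shape[1])
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular covariance in depth computation") from e
    d = Z - mu
    md2 = np.einsum("ij,jk,ik->i", d, inv, d)
    return 1.0 / (1.0 + md2)


def ddplot_r2(real: ClinicalTable, syn: ClinicalTable) -> float:
    """R^2 of the pooled depth-vs-depth scatter against the identity line,
    floored at 0."""
    num = real.schema.continuous_names()
    p = len(num)
    if len(real) < p + 2 or len(syn) < p + 2:
        raise ValueError("need at least p+2 rows per table")
    R = real.df[num].to_numpy(float)
    S = syn.df[num].to_numpy(float)
    pooled = np.vstack([R, S])
    x = _mahalanobis_depth(pooled, R)
    y = _mahalanobis_depth(pooled, S)
    ss_res = ((y - x) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot <= 0:
        return 1.0 if ss_res == 0 else 0.0
    return float(max(0.0, 1.0 - ss_res / ss_tot))


# --------------------------------------------------------------------------
# Data labeling analysis
# --------------------------------------------------------------------------


@dataclass
class DLAResult:
    """Per-classifier detection scores; ``best`` is the classifier with the
    highest F1 (the most restrictive case)."""

    per_classifier: dict[str, dict[str, float]]
    best: str

    @property
    def auc(self) -> float:
        return self.per_classifier[self.best]["auc"]

    @property
    def f1(self) -> float:
        return self.per_classifier[self.best]["f1"]

    @property
    def recall(self) -> float:
        return self.per_classifier[self.best]["recall"]


def _feature_matrix(table: ClinicalTable) -> np.ndarray:
    blocks = []
    for c in table.schema.columns:
        col = table.df[c.name].to_numpy()
        if c.kind == CONTINUOUS:
            blocks.append(col.astype(float)[:, None])
        else:
            onehot = np.zeros((len(col), c.n_levels))
            onehot[np.arange(len(col)), col.astype(int)] = 1.0
            blocks.append(onehot)
    return np.concatenate(blocks, axis=1)


def _roster(seed: int) -> dict:
    return {
        "logistic": LogisticRegression(max_iter=1000),
        "tree": DecisionTreeClassifier(random_state=seed),
        "random_forest": RandomForestClassifier(n_estimators=100, random_state=seed),
        "grad_boost": HistGradientBoostingClassifier(random_state=seed),
        "knn": KNeighborsClassifier(n_neighbors=5),
        "naive_bayes": GaussianNB(),
    }


def dla(
    real: ClinicalTable,
    syn: ClinicalTable,
    test_frac: float = 0.3,
    seed: int = 0,
) -> DLAResult:
    """Real (label 0) vs synthetic (label 1) detection with six standard
    classifier families on one-hot + z-scored features; stratified split."""
    if len(real) < 4 or len(syn) < 4:
        raise ValueError("each class needs at least 4 rows")
    X = np.vstack([_feature_matrix(real), _feature_matrix(syn)])
    y = np.concatenate([np.zeros(len(real)), np.ones(len(syn))])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    X = (X - mu) / sd
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_frac, stratify=y, random_state=seed)
    scores = {}
    for name, clf in _roster(seed).items():
        clf.fit(X_tr, y_tr)
        prob = clf.predict_proba(X_te)[:, 1]
        pred = (prob >= 0.5).astype(int)
        scores[name] = {
            "auc": float(roc_auc_score(y_te, prob)),
            "f1": float(f1_score(y_te, pred)),
            "recall": float(recall_score(y_te, pred)),
        }
    best = max(scores, key=lambda k: scores[k]["f1"])
    return DLAResult(scores, best)
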