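"""Full experimental grid and fold-wise statistical comparison protocol.

A cell is one (model, scenario, node-count) configuration.  Per cell the
protocol is: fit the encoder on the full table, partition (federated cells
only), train ONE model — centralized for the baseline, FedAvg otherwise —
then draw ``folds`` independent synthetic tables of the real table's size
with distinct fold seeds and score each one with the whole fidelity and
privacy battery.  Cell means and standard deviations feed pooled-variance
two-sample t-tests: baseline against every federated cell, and adjacent
node-count pairs (3-5, 5-7, 7-10) within each scenario.

Fold seeds are a pure function of (base seed, cell, fold), so any single
cell can be recomputed bit-identically in isolation.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import fidelity, privacy
from .federate import FedConfig, run_federation
from .fixtures import ClinicalTable, generate_fixture
from .models import CTGANConfig, DiffusionConfig, init_state, sample, train
from .partition import (partition_balanced, partition_dirichlet_noniid,
                        partition_imbalanced)
from .preprocess import fit_transformer

__all__ = [
    "ExperimentConfig",
    "MetricTable",
    "TTestResult",
    "fold_seed",
    "run_experiment",
    "two_sample_t_test",
    "compare",
    "FIDELITY_METRICS",
    "PRIVACY_METRICS",
]

log = logging.getLogger("fedsynth")

FIDELITY_METRICS = ("cs_phik", "dla_auc", "dla_f1", "dla_recall", "vendi",
                    "hellinger_mean", "ddplot_r2")
PRIVACY_METRICS = ("mia", "aia", "linkability", "singling_out")

SCENARIOS = ("baseline", "B", "IB", "IB_non_iid")


@dataclass(frozen=True)
class ExperimentConfig:
    models: tuple[str, ...] = ("ctgan", "diffusion")
    scenarios: tuple[str, ...] = SCENARIOS
    node_counts: tuple[int, ...] = (3, 5, 7, 10)
    folds: int = 10
    epochs: int = 500          # centralized training budget
    rounds: int = 500          # federation rounds (1 local epoch each)
    base_seed: int = 0
    significance: float = 0.05
    minority_frac: float = 0.05
    dirichlet_alpha: float = 10.0
    max_modes: int = 10
    sample_size: int | None = None   # synthetic rows per fold; None = real size
    metrics: tuple[str, ...] = FIDELITY_METRICS + PRIVACY_METRICS
    ctgan: CTGANConfig = field(default_factory=CTGANConfig)
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    privacy_cfg: privacy.PrivacyConfig = field(default_factory=privacy.PrivacyConfig)
    bh_correction: bool = False      # Benjamini-Hochberg over compare() p-values

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not (0 < self.significance < 1):
            raise ValueError("significance must lie in (0, 1)")


@dataclass
class MetricTable:
    """Fold-wise metric rows keyed by (model, scenario, N, fold)."""

    df: pd.DataFrame

    def values(self, model: str, scenario: str, N: int | None, metric: str) -> np.ndarray:
        sel = (self.df["model"] == model) & (self.df["scenario"] == scenario)
        if scenario != "baseline":
            sel &= self.df["N"] == N
        return self.df.loc[sel].sort_values("fold")[metric].to_numpy()

    def summary(self) -> pd.DataFrame:
        metrics = [c for c in self.df.columns
                   if c not in ("model", "scenario", "N", "fold")]
        g = self.df.groupby(["model", "scenario", "N"], dropna=False)[metrics]
        out = g.agg(["mean", "std"])
        out.columns = [f"{m}_{s}" for m, s in out.columns]
        return out.reset_index()


@dataclass
class TTestResult:
    t: float | None
    df: int | None
    p: float | None
    pair: tuple[str, str]
    skipped: bool = False
    reason: str | None = None


def fold_seed(base_seed: int, model: str, scenario: str, N: int | None, fold: int) -> int:
    """Deterministic per-fold seed; a pure function of the cell coordinates."""
    key = f"{base_seed}|{model}|{scenario}|{N}|{fold}".encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=4).digest(), "big") % (2 ** 31)


def _cell_seed(base_seed: int, model: str, scenario: str, N: int | None) -> int:
    return fold_seed(base_seed, model, scenario, N, fold=-1)


def _model_factory(cfg: ExperimentConfig, model: str, tr, schema):
    mcfg = cfg.ctgan if model == "ctgan" else cfg.diffusion
    return lambda seed: init_state(model, tr, schema, mcfg, seed)


def _train_cell(cfg: ExperimentConfig, fixture: ClinicalTable, model: str,
                scenario: str, N: int | None, tr):
    seed = _cell_seed(cfg.base_seed, model, scenario, N)
    factory = _model_factory(cfg, model, tr, fixture.schema)
    if scenario == "baseline":
        state = factory(seed)
        if cfg.epochs > 0:
            train(state, fixture, tr, epochs=cfg.epochs)
        return state
    n = len(fixture)
    if scenario == "B":
        plan = partition_balanced(n, N, seed)
    elif scenario == "IB":
        plan = partition_imbalanced(n, N, cfg.minority_frac, seed)
    elif scenario == "IB_non_iid":
        plan = partition_dirichlet_noniid(
            fixture, N=N, alpha=cfg.dirichlet_alpha, seed=seed)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    fed = FedConfig(N=N, rounds=cfg.rounds, local_epochs=1, seed=seed)
    return run_federation(factory, fixture, plan, tr, fed)


def _evaluate_fold(cfg: ExperimentConfig, fixture: ClinicalTable,
                   syn: ClinicalTable, control: ClinicalTable,
                   so_baseline: ClinicalTable, real_phik,
                   seed: int) -> dict:
    row: dict = {}
    m = cfg.metrics
    if "cs_phik" in m:
        syn_phik = fidelity.phik_matrix(syn)
        row["cs_phik"] = fidelity.matrix_cosine_similarity(real_phik, syn_phik)
    if any(k in m for k in ("dla_auc", "dla_f1", "dla_recall")):
        res = fidelity.dla(fixture, syn, seed=seed)
        row["dla_auc"], row["dla_f1"], row["dla_recall"] = res.auc, res.f1, res.recall
    if "vendi" in m:
        row["vendi"] = fidelity.vendi_score(syn)
    if "hellinger_mean" in m:
        row["hellinger_mean"] = fidelity.mean_hellinger(fixture, syn)
    if "ddplot_r2" in m:
        row["ddplot_r2"] = fidelity.ddplot_r2(fixture, syn)
    pcfg = replace(cfg.privacy_cfg, seed=seed)
    if "mia" in m:
        row["mia"] = privacy.mia_risk(fixture, control, syn, pcfg).risk
    if "aia" in m:
        row["aia"] = privacy.aia_risk(fixture, syn, pcfg).risk
    if "linkability" in m:
        row["linkability"] = privacy.linkability_risk(fixture, syn, cfg=pcfg).risk
    if "singling_out" in m:
        row["singling_out"] = privacy.singling_out_risk(
            fixture, syn, pcfg, baseline_table=so_baseline).risk
    return row


def run_experiment(cfg: ExperimentConfig, fixture: ClinicalTable) -> MetricTable:
    """Run every configured cell; a failing cell is logged and skipped, it
    does not abort the grid."""
    fixture.validate()
    tr = fit_transformer(fixture, cfg.max_modes, seed=cfg.base_seed)
    n_sample = cfg.sample_size or len(fixture)
    control = generate_fixture(fixture.schema, len(fixture),
                               seed=_cell_seed(cfg.base_seed, "control", "-", None))
    so_baseline = generate_fixture(fixture.schema, n_sample,
                                   seed=_cell_seed(cfg.base_seed, "so_base", "-", None))
    real_phik = (fidelity.phik_matrix(fixture)
                 if "cs_phik" in cfg.metrics else None)
    rows = []
    cells: list[tuple[str, str, int | None]] = []
    for model in cfg.models:
        for scenario in cfg.scenarios:
            if scenario == "baseline":
                cells.append((model, scenario, None))
            else:
                cells.extend((model, scenario, N) for N in cfg.node_counts)
    for model, scenario, N in cells:
        label = f"{model}/{scenario}" + (f"/{N}N" if N else "")
        try:
            log.info("training cell %s", label)
            state = _train_cell(cfg, fixture, model, scenario, N, tr)
            for fold in range(cfg.folds):
                fseed = fold_seed(cfg.base_seed, model, scenario, N, fold)
                syn = sample(state, n_sample, seed=fseed)
                row = _evaluate_fold(cfg, fixture, syn, control, so_baseline,
                                     real_phik, fseed)
                rows.append({"model": model, "scenario": scenario,
                             "N": N, "fold": fold, **row})
        except Exception:  # noqa: BLE001 - a cell failure must not kill the grid
            log.exception("cell %s failed; skipping", label)
    return MetricTable(pd.DataFrame(rows))


# --------------------------------------------------------------------------
# Statistics
# --------------------------------------------------------------------------


def two_sample_t_test(a, b, pair: tuple[str, str] = ("a", "b")) -> TTestResult:
    """Pooled-variance Student two-sample t-test, two-sided, df = n1+n2-2.

    Cells whose fold values have zero spread in both groups are skipped
    (flagged), mirroring the convention of reporting no test when the
    standard deviation is zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two folds per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        reason = ("results identical to comparison group"
                  if np.array_equal(a, b) else "standard deviation is zero")
        return TTestResult(None, None, None, pair, skipped=True, reason=reason)
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * va + (n2 - 1) * vb) / df
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), int(df), float(p), pair)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1].clip(0, 1)
    out = np.empty_like(ranked)
    out[order] = ranked
    return out


def compare(table: MetricTable, cfg: ExperimentConfig) -> pd.DataFrame:
    """Baseline-vs-federated and adjacent-node-count t-tests per metric."""
    metrics = [m for m in cfg.metrics if m in table.df.columns]
    recs = []

    def add(model, metric, kind, la, lb, a, b):
        if len(a) == 0 or len(b) == 0:
            recs.append({"model": model, "metric": metric, "comparison": kind,
                         "a": la, "b": lb, "t": None, "df": None, "p": None,
                         "significant": None, "skipped": "cell unavailable"})
            return
        r = two_sample_t_test(a, b, (la, lb))
        recs.append({"model": model, "metric": metric, "comparison": kind,
                     "a": la, "b": lb, "t": r.t, "df": r.df, "p": r.p,
                     "significant": (None if r.skipped else r.p < cfg.significance),
                     "skipped": r.reason})

    for model in cfg.models:
        base_present = "baseline" in cfg.scenarios
        for metric in metrics:
            if base_present:
                base = table.values(model, "baseline", None, metric)
                for scenario in cfg.scenarios:
                    if scenario == "baseline":
                        continue
                    for N in cfg.node_counts:
                        add(model, metric, "baseline_vs_federated",
                            "baseline", f"{scenario}/{N}N",
                            base, table.values(model, scenario, N, metric))
            for scenario in cfg.scenarios:
                if scenario == "baseline":
                    continue
                for Na, Nb in zip(cfg.node_counts[:-1], cfg.node_counts[1:]):
                    add(model, metric, "adjacent_nodes",
                        f"{scenario}/{Na}N", f"{scenario}/{Nb}N",
                        table.values(model, scenario, Na, metric),
                        table.values(model, scenario, Nb, metric))
    out = pd.DataFrame(recs)
    if cfg.bh_correction and len(out):
        mask = out["p"].notna()
        adj = np.full(len(out), np.nan)
        adj[mask.to_numpy()] = _bh_adjust(out.loc[mask, "p"].to_numpy())
        out["p_adjusted"] = adj
        out.loc[mask, "significant"] = out.loc[mask, "p_adjusted"] < cfg.significance
    return out
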