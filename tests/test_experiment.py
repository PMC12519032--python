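"""Fold protocol, seed purity and the statistical comparison machinery."""

import numpy as np
import pytest
from scipy import stats as sps

from fedsynth import (CTGANConfig, ExperimentConfig, compare, fold_seed,
                      generate_fixture, run_experiment, two_sample_t_test)
from fedsynth.experiment import FIDELITY_METRICS, PRIVACY_METRICS, MetricTable


def test_fold_seed_is_pure_and_distinct():
    a = fold_seed(0, "ctgan", "B", 3, 0)
    assert a == fold_seed(0, "ctgan", "B", 3, 0)
    others = {fold_seed(0, "ctgan", "B", 3, f) for f in range(10)}
    assert len(others) == 10
    assert fold_seed(1, "ctgan", "B", 3, 0) != a
    assert all(0 <= s < 2 ** 31 for s in others)


# ----------------------------------------------------------- t-test ----


def test_t_test_identical_samples():
    r = two_sample_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.t == pytest.approx(0.0, abs=1e-12)
    assert r.p == pytest.approx(1.0, abs=1e-12)


def test_t_test_hand_case():
    # pooled t of {1,2,3,4} vs {2,3,4,5}: t = -1.0954, df = 6
    r = two_sample_t_test([1, 2, 3, 4], [2, 3, 4, 5])
    assert r.t == pytest.approx(-1.0954, abs=1e-4)
    assert r.df == 6


def test_t_test_df_is_18_at_ten_folds(rng):
    r = two_sample_t_test(rng.normal(size=10), rng.normal(size=10))
    assert r.df == 18


def test_t_test_matches_brute_force_oracle(rng):
    for _ in range(20):
        a = rng.normal(size=10)
        b = rng.normal(size=10) + rng.normal()
        r = two_sample_t_test(a, b)
        # textbook pooled-variance computation
        sp2 = ((9 * a.var(ddof=1)) + (9 * b.var(ddof=1))) / 18
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 10))
        p = 2 * sps.t.sf(abs(t), 18)
        assert r.t == pytest.approx(t, abs=1e-9)
        assert r.p == pytest.approx(p, abs=1e-9)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert r.t == pytest.approx(ref.statistic, abs=1e-9)


def test_t_test_zero_variance_skipped():
    r = two_sample_t_test([2.0] * 10, [2.0] * 10)
    assert r.skipped and "identical" in r.reason
    r2 = two_sample_t_test([2.0] * 10, [3.0] * 10)
    assert r2.skipped and "zero" in r2.reason


# ----------------------------------------------- fold protocol ----


@pytest.fixture(scope="module")
def stub_run(schema):
    """Untrained generator (epochs = 0) as a stub model: exercises the full
    fold protocol without training cost."""
    fixture = generate_fixture(schema, 300, seed=2)
    cfg = ExperimentConfig(
        models=("ctgan",), scenarios=("baseline", "B"), node_counts=(3,),
        folds=10, epochs=0, rounds=0, base_seed=0,
        ctgan=CTGANConfig(batch_size=100, pac=10))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = run_experiment(cfg, fixture)
    return cfg, table


def test_each_cell_produces_exactly_ten_folds(stub_run):
    cfg, table = stub_run
    counts = table.df.groupby(["model", "scenario"], dropna=False)["fold"].count()
    assert (counts == 10).all()
    assert set(table.df.columns) >= set(FIDELITY_METRICS) | set(PRIVACY_METRICS)


def test_summary_has_mean_and_std_rows(stub_run):
    cfg, table = stub_run
    summ = table.summary()
    assert "cs_phik_mean" in summ.columns and "cs_phik_std" in summ.columns
    assert (summ["dla_auc_std"].fillna(0) >= 0).all()


def test_compare_emits_expected_comparisons(stub_run):
    cfg, table = stub_run
    rep = compare(table, cfg)
    # 1 baseline-vs-federated + 0 adjacent pairs (single node count) per metric
    n_metrics = len([m for m in cfg.metrics if m in table.df.columns])
    assert len(rep) == n_metrics
    assert set(rep["comparison"]) == {"baseline_vs_federated"}


def test_compare_adjacent_pair_count():
    # N in {3,5,7,10} -> exactly 3 adjacent pairs
    cfg = ExperimentConfig(models=("ctgan",), node_counts=(3, 5, 7, 10))
    pairs = list(zip(cfg.node_counts[:-1], cfg.node_counts[1:]))
    assert pairs == [(3, 5), (5, 7), (7, 10)]


def test_compare_flags_identical_cells_non_significant(stub_run):
    cfg, table = stub_run
    df = table.df.copy()
    # overwrite one metric so baseline and federated cells are equal but
    # fold-to-fold variable
    df["vendi"] = np.tile(np.linspace(1, 2, 10), len(df) // 10)
    rep = compare(MetricTable(df), cfg)
    row = rep[(rep["metric"] == "vendi")].iloc[0]
    assert row["t"] == pytest.approx(0.0, abs=1e-12)
    assert row["significant"] == False  # noqa: E712


def test_missing_cell_marked_unavailable(stub_run):
    cfg, table = stub_run
    df = table.df[table.df["scenario"] == "baseline"]
    rep = compare(MetricTable(df), cfg)
    assert (rep["skipped"] == "cell unavailable").any()


def test_rerunning_experiment_reproduces_rows(schema):
    fixture = generate_fixture(schema, 200, seed=3)
    cfg = ExperimentConfig(
        models=("ctgan",), scenarios=("baseline",), node_counts=(3,),
        folds=3, epochs=0, rounds=0, base_seed=1,
        metrics=("hellinger_mean", "vendi"),
        ctgan=CTGANConfig(batch_size=100, pac=10))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = run_experiment(cfg, fixture).df
        b = run_experiment(cfg, fixture).df
    assert a.equals(b)
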