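"""Closed-form oracles and calibration of the fidelity metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fedsynth import (ClinicalTable, ColumnSpec, TableSchema, ddplot_r2, dla,
                      generate_fixture, hellinger_distance,
                      matrix_cosine_similarity, mean_hellinger, phik,
                      phik_matrix, vendi_score)
from fedsynth.fidelity import CorrelationMatrix
from fedsynth.fixtures import CATEGORICAL, CONTINUOUS


# ---------------------------------------------------------------- phik ----


def test_phik_perfect_dependence(rng):
    x = rng.normal(size=3000)
    assert phik(x, x) >= 0.99


def test_phik_independent_binaries_near_zero(rng):
    x = rng.integers(0, 2, 10_000)
    y = rng.integers(0, 2, 10_000)
    assert phik(x, y, CATEGORICAL, CATEGORICAL) < 0.05


def test_phik_symmetric_in_arguments(rng):
    x = rng.normal(size=2000)
    y = 0.5 * x + rng.normal(size=2000)
    assert phik(x, y) == pytest.approx(phik(y, x), abs=1e-9)


def test_phik_constant_column_is_zero(rng):
    x = np.ones(500)
    y = rng.normal(size=500)
    assert phik(x, y) == 0.0


def test_phik_tracks_latent_gaussian_correlation(rng):
    # for a binned bivariate normal, phik estimates the latent rho
    z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=20_000)
    assert phik(z[:, 0], z[:, 1]) == pytest.approx(0.6, abs=0.05)


def test_phik_matrix_properties(small_table):
    M = phik_matrix(small_table).values
    assert np.allclose(M, M.T)
    assert np.allclose(np.diag(M), 1.0)
    assert M.min() >= 0.0 and M.max() <= 1.0


# ------------------------------------------------- cosine similarity ----


def _cm(values):
    values = np.asarray(values, float)
    return CorrelationMatrix(values, [f"c{i}" for i in range(values.shape[0])])


def test_cosine_identity():
    A = _cm([[1, 0.5], [0.5, 1]])
    assert matrix_cosine_similarity(A, A) == pytest.approx(1.0, abs=1e-12)


def test_cosine_orthogonal_triangles():
    A = np.eye(3); A[0, 1] = A[1, 0] = 1.0
    B = np.eye(3); B[0, 2] = B[2, 0] = 1.0
    assert matrix_cosine_similarity(_cm(A), _cm(B)) == pytest.approx(0.0, abs=1e-12)


def test_cosine_hand_case_one_over_sqrt2():
    A = np.eye(3); A[0, 1] = A[1, 0] = 1.0; A[0, 2] = A[2, 0] = 1.0
    B = np.eye(3); B[0, 1] = B[1, 0] = 1.0
    assert matrix_cosine_similarity(_cm(A), _cm(B)) == pytest.approx(
        1 / np.sqrt(2), abs=1e-9)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_cosine_matches_bruteforce_dot_product(seed):
    r = np.random.default_rng(seed)
    A = r.random((12, 12)); A = (A + A.T) / 2; np.fill_diagonal(A, 1)
    B = r.random((12, 12)); B = (B + B.T) / 2; np.fill_diagonal(B, 1)
    iu = np.triu_indices(12, 1)
    x, y = A[iu], B[iu]
    brute = float(x @ y / (np.linalg.norm(x) * np.linalg.norm(y)))
    assert matrix_cosine_similarity(_cm(A), _cm(B)) == pytest.approx(brute, abs=1e-12)


def test_cosine_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        matrix_cosine_similarity(np.eye(3), np.eye(4))


# ----------------------------------------------------------- Vendi ----


def _numeric_table(X):
    p = X.shape[1]
    cols = [ColumnSpec(f"x{i}", CONTINUOUS, ("norm", {"loc": 0, "scale": 1}),
                       (-1e9, 1e9), conditioning=(i == 0)) for i in range(p)]
    schema = TableSchema(cols, n_default=len(X))
    return ClinicalTable(schema, pd.DataFrame(
        {f"x{i}": X[:, i] for i in range(p)}))


def test_vendi_identical_rows_is_one():
    # rank-1 kernel: every row a copy of the same nonzero vector
    t = _numeric_table(np.tile([[1.0, 2.0, -1.0]], (8, 1)))
    assert vendi_score(t, standardize=False) == pytest.approx(1.0, abs=1e-9)
    assert vendi_score(t) == pytest.approx(1.0, abs=1e-9)  # degenerate z-score case


def test_vendi_orthogonal_rows_equals_n():
    # K = I => entropy log n => score n
    t = _numeric_table(np.eye(4))
    assert vendi_score(t, standardize=False) == pytest.approx(4.0, abs=1e-9)


def test_vendi_two_orthogonal_rows_is_two():
    # eigenvalues of K/2 are {1/2, 1/2}
    t = _numeric_table(np.array([[1.0, 1.0], [1.0, -1.0]]))
    assert vendi_score(t, standardize=False) == pytest.approx(2.0, abs=1e-9)


def test_vendi_bounds_on_random_tables(schema):
    t = generate_fixture(schema, 150, seed=11)
    v = vendi_score(t)
    assert 1.0 <= v <= 150.0


def test_vendi_requires_numeric_columns():
    cols = [ColumnSpec("a", CATEGORICAL, (["x", "y"], [0.5, 0.5]), conditioning=True)]
    schema = TableSchema(cols, 4)
    t = ClinicalTable(schema, pd.DataFrame({"a": [0, 1, 0, 1]}))
    with pytest.raises(ValueError, match="continuous"):
        vendi_score(t)


# ------------------------------------------------------- Hellinger ----


def test_hellinger_identical_is_zero(rng):
    x = rng.normal(size=500)
    assert hellinger_distance(x, x, CONTINUOUS) == pytest.approx(0.0, abs=1e-12)


def test_hellinger_disjoint_categorical_is_one():
    a = np.zeros(100, dtype=int)
    b = np.ones(100, dtype=int)
    assert hellinger_distance(a, b, CATEGORICAL) == pytest.approx(1.0, abs=1e-12)


def test_hellinger_bernoulli_closed_form():
    # p = Bernoulli(0.5), q = Bernoulli(1.0): H = sqrt(1 - sqrt(0.5))
    a = np.array([0] * 50 + [1] * 50)
    b = np.ones(80, dtype=int)
    expected = np.sqrt(1 - np.sqrt(0.5))
    assert hellinger_distance(a, b, CATEGORICAL) == pytest.approx(expected, abs=1e-12)


def test_mean_hellinger_zero_on_self(small_table):
    assert mean_hellinger(small_table, small_table) == pytest.approx(0.0, abs=1e-12)


# --------------------------------------------------------- DD-plot ----


def test_ddplot_identity_on_self(small_table):
    assert ddplot_r2(small_table, small_table) == pytest.approx(1.0, abs=1e-9)


def test_ddplot_gross_shift_collapses(schema):
    real = generate_fixture(schema, 400, seed=1)
    syn = generate_fixture(schema, 400, seed=2)
    df = syn.df.copy()
    for c in schema.continuous_names():
        df[c] = df[c] + 10 * real.df[c].std()
    shifted = ClinicalTable(schema, df)
    assert ddplot_r2(real, shifted) < 0.2


def test_ddplot_invariant_to_row_order(schema):
    real = generate_fixture(schema, 300, seed=1)
    syn = generate_fixture(schema, 300, seed=2)
    shuffled = syn.subset(np.random.default_rng(0).permutation(300))
    assert ddplot_r2(real, syn) == pytest.approx(ddplot_r2(real, shuffled), abs=1e-9)


# -------------------------------------------------------------- DLA ----


def test_dla_null_calibrated_on_held_out_real(schema):
    t = generate_fixture(schema, 1000, seed=4)
    real, held = t.subset(range(500)), t.subset(range(500, 1000))
    res = dla(real, held, seed=0)
    assert 0.45 <= res.auc <= 0.60


def test_dla_detects_gross_shift(schema):
    real = generate_fixture(schema, 400, seed=5)
    syn = generate_fixture(schema, 400, seed=6)
    df = syn.df.copy()
    df["age"] = df["age"] + 20 * real.df["age"].std()
    shifted = ClinicalTable(schema, df)
    res = dla(real, shifted, seed=0)
    assert res.auc >= 0.99


def test_dla_recall_is_synthetic_as_positive(schema):
    real = generate_fixture(schema, 200, seed=7)
    syn = generate_fixture(schema, 200, seed=8)
    res = dla(real, syn, seed=0)
    for scores in res.per_classifier.values():
        assert 0.0 <= scores["recall"] <= 1.0
    assert res.best in res.per_classifier
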