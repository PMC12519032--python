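"""Privacy attack saturation, null calibration and Gower metric properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fedsynth import (PrivacyConfig, aia_risk, generate_fixture, gower_distance,
                      gower_matrix, linkability_risk, mia_risk,
                      singling_out_risk)
from fedsynth.fixtures import ClinicalTable


CFG = PrivacyConfig(seed=0)


# ------------------------------------------------------------- Gower ----


def test_gower_identity(small_table):
    rec = small_table.df.iloc[0]
    assert gower_distance(rec, rec, small_table.schema) == 0.0


def test_gower_full_categorical_mismatch(small_table):
    schema = small_table.schema
    a = small_table.df.iloc[0].copy()
    b = a.copy()
    for c in schema.columns:
        if c.kind == "categorical":
            b[c.name] = (a[c.name] + 1) % c.n_levels
        else:
            b[c.name] = a[c.name]  # equal numeric -> contributes 0
    d = gower_distance(a, b, schema)
    n_cat = len(schema.categorical_names())
    assert d == pytest.approx(n_cat / 12)


def test_gower_numeric_hand_case(small_table):
    schema = small_table.schema
    a = small_table.df.iloc[0].copy()
    b = a.copy()
    b["age"] = a["age"] + 5.0
    ranges = {c.name: 10.0 for c in schema.columns if c.kind == "continuous"}
    # one differing numeric column: |5| / 10 / 12 columns
    assert gower_distance(a, b, schema, ranges) == pytest.approx(0.5 / 12, abs=1e-12)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10 ** 6))
def test_gower_is_a_metric_on_random_triples(seed):
    r = np.random.default_rng(seed)
    from fedsynth import build_aml_schema

    schema = build_aml_schema()
    t = generate_fixture(schema, 3, seed=seed % (2 ** 31))
    a, b, c = (t.df.iloc[i] for i in range(3))
    dab = gower_distance(a, b, schema)
    dba = gower_distance(b, a, schema)
    dac = gower_distance(a, c, schema)
    dcb = gower_distance(c, b, schema)
    assert dab == pytest.approx(dba, abs=1e-12)          # symmetry
    assert 0.0 <= dab <= 1.0
    assert dab <= dac + dcb + 1e-12                      # triangle inequality


def test_gower_matrix_matches_recordwise(small_table):
    sub = small_table.subset(range(6))
    M = gower_matrix(sub, sub)
    for i in range(6):
        for j in range(6):
            d = gower_distance(sub.df.iloc[i], sub.df.iloc[j], sub.schema,
                               ranges={c.name: sub.df[c.name].max() - sub.df[c.name].min()
                                       for c in sub.schema.columns
                                       if c.kind == "continuous"})
            assert M[i, j] == pytest.approx(d, abs=1e-6)


# ----------------------------------------------------- MIA saturation ----


def test_mia_copy_of_train_is_full_risk(schema):
    train = generate_fixture(schema, 200, seed=1)
    control = generate_fixture(schema, 200, seed=2)
    res = mia_risk(train, control, train, CFG)
    assert res.risk == pytest.approx(1.0)


def test_mia_train_equals_control_is_zero_risk(schema):
    t = generate_fixture(schema, 200, seed=1)
    syn = generate_fixture(schema, 200, seed=3)
    assert mia_risk(t, t, syn, CFG).risk == 0.0


def test_mia_independent_synthetic_near_zero(schema):
    train = generate_fixture(schema, 1000, seed=1)
    control = generate_fixture(schema, 1000, seed=2)
    syn = generate_fixture(schema, 1000, seed=3)
    assert mia_risk(train, control, syn, CFG).risk <= 0.05


# ----------------------------------------------------------- AIA ----


def test_aia_copy_saturates(schema):
    real = generate_fixture(schema, 300, seed=1)
    res = aia_risk(real, real, CFG)
    assert res.success_rate == pytest.approx(1.0)


def test_aia_numeric_tolerance_rule(schema):
    # range 10, truth 50, prediction 50.4 -> |0.4| <= 0.05 * 10 succeeds
    assert abs(50.4 - 50.0) <= 0.05 * 10


def test_aia_independent_synthetic_near_zero(schema):
    real = generate_fixture(schema, 1000, seed=4)
    syn = generate_fixture(schema, 1000, seed=5)
    assert aia_risk(real, syn, CFG).risk <= 0.05


# ----------------------------------------------------- linkability ----


def test_linkability_copy_links_every_record(schema):
    # views each contain continuous columns so every half-record is unique;
    # an all-categorical view would collide across patients and dilute the
    # saturation case
    real = generate_fixture(schema, 300, seed=1)
    res = linkability_risk(real, real,
                           colsA=["age", "wbc", "hb"],
                           colsB=["platelets", "bm_blasts", "sex"], cfg=CFG)
    assert res.success_rate == pytest.approx(1.0)
    assert res.risk > 0.9


def test_linkability_independent_near_zero(schema):
    real = generate_fixture(schema, 1000, seed=6)
    syn = generate_fixture(schema, 1000, seed=7)
    assert linkability_risk(real, syn, cfg=CFG).risk <= 0.05


def test_linkability_overlapping_views_rejected(small_table):
    names = small_table.schema.names
    with pytest.raises(ValueError, match="disjoint"):
        linkability_risk(small_table, small_table,
                         colsA=names[:7], colsB=names[5:], cfg=CFG)


# ---------------------------------------------------- singling out ----


def test_singling_out_duplicated_real_table_is_zero(schema):
    import pandas as pd

    half = generate_fixture(schema, 150, seed=1)
    dup = ClinicalTable(schema, pd.concat([half.df, half.df], ignore_index=True))
    syn = generate_fixture(schema, 300, seed=2)
    res = singling_out_risk(dup, syn, PrivacyConfig(seed=0, n_attacks=200))
    assert res.success_rate == 0.0


def test_singling_out_copy_with_tight_tolerance_saturates(schema):
    real = generate_fixture(schema, 300, seed=3)
    cfg = PrivacyConfig(seed=0, aia_tolerance=1e-9, n_attacks=200)
    res = singling_out_risk(real, real, cfg)
    assert res.success_rate == pytest.approx(1.0)


def test_risks_bounded(schema):
    real = generate_fixture(schema, 300, seed=8)
    syn = generate_fixture(schema, 300, seed=9)
    for res in (mia_risk(real, generate_fixture(schema, 300, seed=10), syn, CFG),
                aia_risk(real, syn, CFG),
                linkability_risk(real, syn, cfg=CFG),
                singling_out_risk(real, syn, PrivacyConfig(seed=0, n_attacks=100))):
        assert 0.0 <= res.risk <= 1.0
        assert 0.0 <= res.success_rate <= 1.0
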