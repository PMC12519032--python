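"""Generative model contracts: determinism, weight views, recovery runs."""

import numpy as np
import pandas as pd
import pytest

from fedsynth import (CTGANConfig, ClinicalTable, ColumnSpec, DiffusionConfig,
                      TableSchema, fit_transformer, generate_fixture,
                      get_weights, init_state, sample, set_weights, train)
from fedsynth.fixtures import CATEGORICAL, CONTINUOUS
from fedsynth.models import beta_schedule

SMALL_CTGAN = CTGANConfig(batch_size=100, pac=10)
SMALL_DIFF = DiffusionConfig(T=50, batch_size=100)


def _binary_table(p1=0.8, n=2000, seed=0):
    rng = np.random.default_rng(seed)
    cols = [
        ColumnSpec("x", CONTINUOUS, ("norm", {"loc": 0, "scale": 1}), (-5, 5),
                   conditioning=True),
        ColumnSpec("flag", CATEGORICAL, (["0", "1"], [1 - p1, p1])),
    ]
    schema = TableSchema(cols, n)
    df = pd.DataFrame({"x": rng.normal(size=n).clip(-5, 5),
                       "flag": (rng.random(n) < p1).astype(int)})
    return ClinicalTable(schema, df)


@pytest.fixture(scope="module", params=["ctgan", "diffusion"])
def kind(request):
    return request.param


def _cfg(kind):
    return SMALL_CTGAN if kind == "ctgan" else SMALL_DIFF


def test_zero_epochs_is_noop_with_warning(kind, small_table, small_transformer):
    st = init_state(kind, small_transformer, small_table.schema, _cfg(kind), seed=0)
    w0 = get_weights(st)
    with pytest.warns(UserWarning, match="skipped"):
        train(st, small_table, small_transformer, epochs=0)
    assert np.array_equal(get_weights(st), w0)


def test_training_is_deterministic(kind, small_table, small_transformer):
    runs = []
    for _ in range(2):
        st = init_state(kind, small_transformer, small_table.schema, _cfg(kind), seed=3)
        train(st, small_table, small_transformer, epochs=2)
        runs.append(get_weights(st))
    assert np.array_equal(runs[0], runs[1])


def test_chunked_training_equals_one_run(kind, small_table, small_transformer):
    a = init_state(kind, small_transformer, small_table.schema, _cfg(kind), seed=3)
    train(a, small_table, small_transformer, epochs=4)
    b = init_state(kind, small_transformer, small_table.schema, _cfg(kind), seed=3)
    for _ in range(4):
        train(b, small_table, small_transformer, epochs=1)
    assert np.array_equal(get_weights(a), get_weights(b))


def test_weight_round_trip(kind, small_table, small_transformer):
    st = init_state(kind, small_transformer, small_table.schema, _cfg(kind), seed=0)
    v = get_weights(st)
    set_weights(st, v * 0.5)
    assert np.array_equal(get_weights(st), v * 0.5)
    with pytest.raises(ValueError, match="length"):
        set_weights(st, v[:-1])


def test_set_get_roundtrip_preserves_sampling(kind, small_table, small_transformer):
    st = init_state(kind, small_transformer, small_table.schema, _cfg(kind), seed=1)
    ref = sample(st, 50, seed=9).df
    set_weights(st, get_weights(st))
    assert sample(st, 50, seed=9).df.equals(ref)


def test_sampling_is_deterministic_and_schema_valid(kind, small_table,
                                                    small_transformer):
    st = init_state(kind, small_transformer, small_table.schema, _cfg(kind), seed=2)
    a = sample(st, 120, seed=4)
    b = sample(st, 120, seed=4)
    assert a.df.equals(b.df)
    a.validate()
    assert a.df.shape == (120, 12)
    with pytest.raises(ValueError):
        sample(st, 0, seed=1)


def test_ctgan_recovers_binary_frequency():
    table = _binary_table(p1=0.8)
    tr = fit_transformer(table, max_modes=3, seed=0)
    st = init_state("ctgan", tr, table.schema, CTGANConfig(batch_size=500, pac=10),
                    seed=5)
    train(st, table, tr, epochs=60)
    syn = sample(st, 5000, seed=6)
    assert 0.7 <= syn.df["flag"].mean() <= 0.9


def test_diffusion_alpha_bar_below_one_percent():
    cfg = DiffusionConfig()  # T = 500, linear schedule 1e-4 .. 0.02
    abar_T = np.prod(1.0 - beta_schedule(cfg))
    assert abar_T < 0.01


def test_diffusion_recovers_two_mode_mixture():
    rng = np.random.default_rng(1)
    vals = np.concatenate([rng.normal(-4, 0.5, 1000), rng.normal(4, 0.5, 1000)])
    cols = [ColumnSpec("x", CONTINUOUS, ("norm", {"loc": 0, "scale": 4}), (-8, 8),
                       conditioning=True)]
    schema = TableSchema(cols, 2000)
    table = ClinicalTable(schema, pd.DataFrame({"x": vals}))
    tr = fit_transformer(table, max_modes=5, seed=0)
    st = init_state("diffusion", tr, schema, DiffusionConfig(T=100, batch_size=500),
                    seed=7)
    train(st, table, tr, epochs=150)
    syn = sample(st, 2000, seed=8).df["x"].to_numpy()
    lo_mass = (syn < 0).mean()
    assert 0.3 <= lo_mass <= 0.7
    # both modes present, not a single central blob
    assert (syn < -2).mean() > 0.2 and (syn > 2).mean() > 0.2


def test_trained_model_beats_untrained_on_detection(schema):
    # full-size fixture: at reduced training scale the trained generator's
    # samples are harder to detect than an untrained generator's
    table = generate_fixture(schema, schema.n_default, seed=1)
    tr = fit_transformer(table, seed=0)
    untrained = init_state("ctgan", tr, schema, CTGANConfig(), seed=1)
    trained = init_state("ctgan", tr, schema, CTGANConfig(), seed=1)
    train(trained, table, tr, epochs=100)
    from fedsynth import dla

    auc_un = dla(table, sample(untrained, 1540, seed=2), seed=0).auc
    auc_tr = dla(table, sample(trained, 1540, seed=2), seed=0).auc
    assert auc_tr < auc_un


def test_config_invariants():
    with pytest.raises(ValueError, match="pac"):
        CTGANConfig(batch_size=501)
    with pytest.raises(ValueError, match="beta"):
        DiffusionConfig(beta_start=0.5, beta_end=0.1)
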