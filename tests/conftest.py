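import numpy as np
import pytest

from fedsynth import build_aml_schema, fit_transformer, generate_fixture


@pytest.fixture(scope="session")
def schema():
    return build_aml_schema()


@pytest.fixture(scope="session")
def small_table(schema):
    """300-row draw of the default schema; shared read-only across tests."""
    return generate_fixture(schema, 300, seed=1)


@pytest.fixture(scope="session")
def small_transformer(small_table):
    return fit_transformer(small_table, max_modes=10, seed=0)


@pytest.fixture(scope="session")
def big_table(schema):
    """20k-row draw for marginal/copula checks."""
    return generate_fixture(schema, 20_000, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
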