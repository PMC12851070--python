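import pytest

from sbsif_claims.synthetic import SyntheticConfig, default_registry, generate_database


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        seed=11, n_true_cases=8, n_near_misses_per_rule=2, n_background=40
    )


@pytest.fixture(scope="session")
def small_db(small_config):
    """Small synthetic database with labels (8 true cases, 14 near-misses, 40 background)."""
    return generate_database(small_config)
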