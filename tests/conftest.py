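import pytest

from liversim import (
    ReplicationConfig,
    ScenarioConfig,
    default_life_table,
    default_registry,
)


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def registry(life_table):
    return default_registry(life_table=life_table)


@pytest.fixture()
def base_scenario(registry, life_table):
    return ScenarioConfig(strategy=1, registry=registry, life_table=life_table)


@pytest.fixture()
def small_config():
    """A handful of replications — enough to exercise every code path."""
    return ReplicationConfig(seed=42, replications=5)
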