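import pytest

from cdti import builtin_fixture, generate_random_record


@pytest.fixture(scope="session")
def reset_o_record():
    return builtin_fixture("reset_o")


@pytest.fixture(scope="session")
def ct132_record():
    return builtin_fixture("ct132")


@pytest.fixture(scope="session")
def record_corpus():
    """500 deterministic random records exercising every tier and enum."""
    return [generate_random_record(seed) for seed in range(500)]
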