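import pytest

from vacause import builtin_definitions, default_codebook, default_hierarchies
from vacause.data_model import VARecord


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture(scope="session")
def definitions(codebook):
    return builtin_definitions(codebook)


@pytest.fixture(scope="session")
def hierarchies():
    return default_hierarchies()


def make_record(record_id="r1", age=400, **responses):
    """Child record (age in days) with the given symptom responses."""
    return VARecord(record_id=record_id, age_at_death_days=age, responses=responses)


@pytest.fixture
def record_factory():
    return make_record
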