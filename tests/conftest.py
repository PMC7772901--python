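import pytest
from hypothesis import HealthCheck, settings

from stresswear import SyntheticSpec, generate_dataset, segment_records

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture])
settings.load_profile("suite")

#: tiny study: 2 subjects, 15 s per condition — enough for 9 windows each
TINY_SPEC = SyntheticSpec(
    n_subjects=2, schedule=((1, 15.0), (2, 15.0), (3, 15.0)), seed=11)


@pytest.fixture(scope="session")
def tiny_records():
    return generate_dataset(TINY_SPEC)


@pytest.fixture(scope="session")
def tiny_record(tiny_records):
    return tiny_records[0]


@pytest.fixture(scope="session")
def chest_windows(tiny_records):
    return segment_records(tiny_records, site="chest")


@pytest.fixture(scope="session")
def wrist_windows(tiny_records):
    return segment_records(tiny_records, site="wrist")
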