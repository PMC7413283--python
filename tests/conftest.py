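import numpy as np
import pytest

from actimpute import RecordSet, SynthParams, generate_dataset, preprocess
from actimpute.records import ActivityRecord


@pytest.fixture(scope="session")
def full_day_set() -> RecordSet:
    """40 complete full-day synthetic records."""
    return generate_dataset(SynthParams(n_subjects=20, days_per_subject=2, rng_seed=11))


@pytest.fixture(scope="session")
def windowed_set(full_day_set) -> RecordSet:
    """The same records after completeness filtering and window extraction."""
    return preprocess(full_day_set)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_record(values, subject="S0", day=0, axis="uniaxial") -> ActivityRecord:
    return ActivityRecord(subject_id=subject, day_index=day, values=np.asarray(values, float), axis_kind=axis)
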