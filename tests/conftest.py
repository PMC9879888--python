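import numpy as np
import pytest

from phjoint.data_model import (
    EventStatus,
    LongitudinalObservation,
    Sex,
    SubjectRecord,
)


@pytest.fixture
def toy_subjects() -> list[SubjectRecord]:
    return [
        SubjectRecord("A", 10.0, Sex.female, 0.0, 3.0, EventStatus.kidney_failure),
        SubjectRecord("B", 25.0, Sex.male, 0.0, 8.0, EventStatus.censored),
        SubjectRecord("C", 5.0, Sex.female, 0.0, 6.0, EventStatus.kidney_failure),
    ]


@pytest.fixture
def toy_observations() -> list[LongitudinalObservation]:
    # subject A: the asynchronous-visit worked example (POX {0,2}, UOX {1},
    # eGFR {0, 1.5}, event at 3)
    obs = [
        LongitudinalObservation("A", "POX", 0.0, 8.0),
        LongitudinalObservation("A", "POX", 2.0, 12.0),
        LongitudinalObservation("A", "UOX", 1.0, 1.5),
        LongitudinalObservation("A", "eGFR", 0.0, 80.0),
        LongitudinalObservation("A", "eGFR", 1.5, 55.0),
        LongitudinalObservation("B", "POX", 0.0, 5.0),
        LongitudinalObservation("B", "UOX", 0.0, 1.2),
        LongitudinalObservation("B", "eGFR", 0.0, 95.0),
        LongitudinalObservation("C", "eGFR", 0.5, 70.0),
        LongitudinalObservation("C", "eGFR", 4.0, 40.0),
        LongitudinalObservation("C", "UOX", 2.0, 2.0),
    ]
    return obs


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220901)
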