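import numpy as np
import pytest

from sourcesig.ehr_data import (
    CodeEvent,
    Demographics,
    LabObservation,
    MedicationMention,
    PatientRecord,
    VariableCatalog,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_record(
    record_id="r1",
    span=1000.0,
    labs=(),
    codes=(),
    meds=(),
    sex="female",
    race="white",
    birth=-40 * 365.25,
    index_day=None,
    label=None,
):
    return PatientRecord(
        record_id=record_id,
        span_days=span,
        labs=[LabObservation(t, d, v) for t, d, v in labs],
        codes=[CodeEvent(c, d) for c, d in codes],
        meds=[MedicationMention(m, d) for m, d in meds],
        demographics=Demographics(sex, race, birth),
        index_day=index_day,
        label=label,
    )


@pytest.fixture
def small_cohort():
    recs = [
        make_record(
            "a",
            span=800.0,
            labs=[("glucose", 10.0, 5.0), ("glucose", 400.0, 6.0), ("sodium", 200.0, 140.0)],
            codes=[("copd", 100.0), ("copd", 300.0), ("nodule", 500.0)],
            meds=[("statin", 250.0)],
            sex="male",
            index_day=500.0,
        ),
        make_record(
            "b",
            span=1200.0,
            labs=[("glucose", 50.0, 7.0)],
            codes=[("nodule", 900.0), ("malig", 905.0)],
            sex="male",
            race="black",
            index_day=900.0,
        ),
        make_record("c", span=600.0, sex="female", index_day=400.0),
    ]
    return recs


@pytest.fixture
def small_catalog(small_cohort):
    return VariableCatalog.from_records(small_cohort)
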