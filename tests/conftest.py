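import numpy as np
import pytest
from hypothesis import settings

from cdid.data_model import PatientRecord

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_record(**kw) -> PatientRecord:
    """A clean in-range patient-year record, overridable per field."""
    base = dict(system_id="s1", clinic_id="c1", year=2009, a1c=7.2, ldl=110.0,
                sbp=128.0, dbp=80.0, commercial=True, age=55.0, female=False,
                ivd=False, diabetes_type=2, wlth=0.1, inc=-0.2, nhw=0.8,
                a1c_date_valid=True, ldl_date_valid=True)
    base.update(kw)
    return PatientRecord(**base)


@pytest.fixture
def filter_fixture():
    """Eight records: one violation of each exclusion rule plus three clean rows."""
    return [
        make_record(clinic_id="c1"),
        make_record(clinic_id="c2", a1c_date_valid=False),       # invalid date
        make_record(clinic_id="c3", a1c=2.9),                    # A1c below range
        make_record(clinic_id="c4", ldl=1200.0),                 # LDL above range
        make_record(clinic_id="c5", sbp=120.0, dbp=130.0),       # SBP below DBP
        make_record(clinic_id="c6", diabetes_type=1),            # Type 1
        make_record(clinic_id="c7"),
        make_record(clinic_id="c8", year=2012),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
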