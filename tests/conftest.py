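import numpy as np
import pytest

from prostage.data import Label, PatientRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """Six hand-written labelled patients covering both classes."""
    return [
        PatientRecord(psa=4.2, gleason="6", clinical_t="T1c", path_t="pT2a", path_n="pN0"),
        PatientRecord(psa=7.8, gleason="7(3+4)", clinical_t="T2a", path_t="pT2b", path_n="pN0"),
        PatientRecord(psa=15.0, gleason="8", clinical_t="T2c", path_t="pT3a", path_n="pN0"),
        PatientRecord(psa=32.5, gleason="9", clinical_t="T3a", path_t="pT3b", path_n="pN1"),
        PatientRecord(psa=5.1, gleason="6", clinical_t="T1b", path_t="pT2c", path_n="pN0"),
        PatientRecord(psa=22.0, gleason="7(4+3)", clinical_t="T3b", path_t="pT3c", path_n="pN0"),
    ]
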