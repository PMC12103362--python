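import hypothesis
import pytest

from aav_classify import AncaSerology, PatientRecord

hypothesis.settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=100
)
hypothesis.settings.load_profile("default")


@pytest.fixture
def make_record():
    """Factory for records with an established vasculitis diagnosis."""

    def _make(patient_id: str = "p1", **kwargs) -> PatientRecord:
        kwargs.setdefault("vasculitis_diagnosis_established", True)
        return PatientRecord(patient_id=patient_id, **kwargs)

    return _make


@pytest.fixture
def dual_scoring_record(make_record):
    """MPO+ and PR3+ with pauci-immune GN: meets both 2022 MPA and GPA scores."""
    return make_record(
        "dual",
        serology=AncaSerology(elisa_mpo="positive", elisa_pr3="positive"),
        pauci_immune_gn="present",
    )


@pytest.fixture
def egpa_record(make_record):
    """Obstructive airway disease with eosinophils >= 1 x10^9/L."""
    return make_record(
        "egpa", obstructive_airway_disease=True, eosinophil_count=1.5
    )
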