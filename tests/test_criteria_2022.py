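"""Itemized 2022 ACR/EULAR scores: worked totals, thresholds, properties."""

import pytest
from hypothesis import given, strategies as st

from aav_classify import (
    AncaSerology,
    EntryConditionError,
    HistologyFinding,
    PatientRecord,
    SubtypeLabel,
    classify_acr_eular_2022,
    score_egpa_2022,
    score_gpa_2022,
    score_mpa_2022,
)
from aav_classify.criteria_2022 import default_config, score_subtype_2022

MPO_POS = AncaSerology(elisa_mpo="positive")
PR3_POS = AncaSerology(elisa_pr3="positive")
BOTH_POS = AncaSerology(elisa_mpo="positive", elisa_pr3="positive")


@pytest.mark.parametrize(
    "scorer, kwargs, total, met",
    [
        # GPA: PR3+ with pauci-immune GN scores 5+1-1(MPO unknown? no: MPO untested -> 0)
        (score_gpa_2022,
         dict(serology=PR3_POS, pauci_immune_gn="present"), 6, True),
        (score_gpa_2022, {}, 0, False),
        (score_gpa_2022,
         dict(serology=MPO_POS, nasal_involvement=True), 2, False),
        # MPA
        (score_mpa_2022,
         dict(serology=BOTH_POS, pauci_immune_gn="present"), 8, True),
        (score_mpa_2022,
         dict(serology=MPO_POS, eosinophil_count=1.2), 2, False),
        (score_mpa_2022, {}, 0, False),
        (score_mpa_2022,
         dict(serology=MPO_POS, pauci_immune_gn="present"), 9, True),
        # EGPA
        (score_egpa_2022,
         dict(obstructive_airway_disease=True, eosinophil_count=1.5), 8, True),
        (score_egpa_2022, {}, 0, False),
        (score_egpa_2022,
         dict(nasal_polyps=True, serology=PR3_POS), 0, False),
    ],
)
def test_worked_score_totals(make_record, scorer, kwargs, total, met):
    score = scorer(make_record(**kwargs))
    assert score.total == total
    assert score.met is met
    assert score.total == sum(c.points for c in score.contributions)


def test_pr3_positive_gpa_example_counts_pauci_immune_gn(make_record):
    score = score_gpa_2022(
        make_record(serology=PR3_POS, pauci_immune_gn="present")
    )
    fired = {c.item_id for c in score.contributions if c.fired}
    assert fired == {"pr3_or_c_anca_positive", "pauci_immune_gn_on_biopsy"}


def test_unknown_inputs_contribute_zero_with_note(make_record):
    score = score_gpa_2022(make_record())  # no biopsy, no serology, no labs
    noted = {c.item_id for c in score.contributions if c.note == "unknown-input"}
    assert "granuloma_on_biopsy" in noted
    assert "pr3_or_c_anca_positive" in noted
    assert "eosinophil_count_ge_1e9_per_l" in noted
    assert all(c.points == 0 for c in score.contributions if c.note)


def test_eosinophil_threshold_is_closed(make_record):
    exactly_one = make_record(obstructive_airway_disease=True, eosinophil_count=1.0)
    assert score_egpa_2022(exactly_one).total == 8


def test_entry_condition_enforced():
    record = PatientRecord(patient_id="p1")  # diagnosis not established
    with pytest.raises(EntryConditionError):
        score_gpa_2022(record)
    with pytest.raises(EntryConditionError):
        classify_acr_eular_2022(record)


def test_multi_label_and_empty_classifications(make_record, dual_scoring_record):
    dual = classify_acr_eular_2022(dual_scoring_record)
    assert dual.labels == frozenset({SubtypeLabel.MPA, SubtypeLabel.GPA})
    nothing = classify_acr_eular_2022(make_record())
    assert nothing.labels == frozenset({SubtypeLabel.UNCLASSIFIED})
    mpa = classify_acr_eular_2022(
        make_record(serology=MPO_POS, pauci_immune_gn="present")
    )
    assert mpa.labels == frozenset({SubtypeLabel.MPA})


# --- property tests ---------------------------------------------------------

_TOGGLEABLE = {
    "nasal_involvement": st.booleans(),
    "cartilaginous_involvement": st.booleans(),
    "hearing_loss": st.booleans(),
    "obstructive_airway_disease": st.booleans(),
    "nasal_polyps": st.booleans(),
    "mononeuritis_multiplex": st.booleans(),
    "hematuria": st.booleans(),
    "pulmonary_nodules_mass_cavitation": st.booleans(),
    "sinonasal_inflammation_or_mastoiditis_imaging": st.booleans(),
    "lung_fibrosis_or_ild": st.booleans(),
    "eosinophil_count": st.none() | st.floats(0, 10, allow_nan=False),
    "pauci_immune_gn": st.sampled_from(["present", "absent", "no_biopsy"]),
    "granulomatous_inflammation": st.sampled_from(["present", "absent", "no_biopsy"]),
    "eosinophil_predominant_extravascular_inflammation": st.sampled_from(
        ["present", "absent", "no_biopsy"]
    ),
}

record_strategy = st.fixed_dictionaries(_TOGGLEABLE).map(
    lambda kw: PatientRecord(
        patient_id="h", vasculitis_diagnosis_established=True, **kw
    )
)


@given(record=record_strategy, subtype=st.sampled_from(["GPA", "MPA", "EGPA"]))
def test_toggling_one_boolean_item_moves_total_by_its_weight(record, subtype):
    config = default_config()
    base = score_subtype_2022(record, subtype, config)
    for item in config.subtypes[subtype]["items"]:
        field = item["field"]
        if field not in PatientRecord.model_fields or not isinstance(
            getattr(record, field), bool
        ):
            continue
        flipped = record.model_copy(update={field: not getattr(record, field)})
        delta = score_subtype_2022(flipped, subtype, config).total - base.total
        expected = item["weight"] if not getattr(record, field) else -item["weight"]
        assert delta == expected


@given(record=record_strategy, subtype=st.sampled_from(["GPA", "MPA", "EGPA"]))
def test_resolving_unknowns_to_negative_never_changes_totals(record, subtype):
    base = score_subtype_2022(record, subtype).total
    update = {}
    if record.eosinophil_count is None:
        update["eosinophil_count"] = 0.0
    for field in ("pauci_immune_gn", "granulomatous_inflammation",
                  "eosinophil_predominant_extravascular_inflammation"):
        if getattr(record, field) is HistologyFinding.NO_BIOPSY:
            update[field] = HistologyFinding.ABSENT
    if update:
        resolved = record.model_copy(update=update)
        assert score_subtype_2022(resolved, subtype).total == base
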