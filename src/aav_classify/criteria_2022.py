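"""The 2022 ACR/EULAR weighted classification criteria for GPA, MPA, EGPA.

Each subtype has an additive score over clinical, serological, imaging and
histology items with signed integer weights and a threshold (GPA >= 5,
MPA >= 5, EGPA >= 6).  The criteria carry no classification sequence, so a
patient may meet several scores at once (duplicate classification) or none.

Item weights and thresholds ship in a versioned JSON config
(``data/acr_eular_2022.json``) and may be overridden wholesale, e.g. to
experiment with alternative weightings.  Items whose inputs are unknown
(no biopsy, eosinophils not measured, serology untested) contribute zero
points and are annotated rather than failing the score, which keeps the
instruments applicable to retrospective tables with missing work-ups.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Optional

from pydantic import BaseModel

from .core import (
    ClassificationResult,
    HistologyFinding,
    PatientRecord,
    SubtypeLabel,
    System,
    Tristate,
)

SUBTYPES_2022 = ("GPA", "MPA", "EGPA")


class EntryConditionError(ValueError):
    """The 2022 scores were applied before a vasculitis diagnosis was made."""


class ItemContribution(BaseModel):
    item_id: str
    fired: bool
    points: int
    note: Optional[str] = None


class CriterionScore(BaseModel):
    """Itemized 2022 ACR/EULAR score for one subtype."""

    subtype: SubtypeLabel
    contributions: tuple[ItemContribution, ...]
    total: int
    threshold: int
    met: bool


class CriteriaConfig2022(BaseModel):
    """Parsed weights/thresholds config for the three 2022 instruments."""

    version: str
    anca_precedence: str
    subtypes: dict[str, dict]

    @classmethod
    def load_default(cls) -> "CriteriaConfig2022":
        text = (
            resources.files("aav_classify.data")
            .joinpath("acr_eular_2022.json")
            .read_text()
        )
        return cls(**json.loads(text))

    @classmethod
    def load(cls, path) -> "CriteriaConfig2022":
        with open(path) as handle:
            return cls(**json.load(handle))


_DEFAULT_CONFIG: Optional[CriteriaConfig2022] = None


def default_config() -> CriteriaConfig2022:
    global _DEFAULT_CONFIG
    if _DEFAULT_CONFIG is None:
        _DEFAULT_CONFIG = CriteriaConfig2022.load_default()
    return _DEFAULT_CONFIG


def _item_status(record: PatientRecord, field: str, policy: str) -> Optional[bool]:
    """Evaluate one config field on a record.

    Returns True/False when determined and ``None`` when the underlying
    input is unknown (untested serology, unmeasured eosinophils, no biopsy).
    """
    if field == "pr3_or_c_positive":
        status = record.serology.pr3_or_c_status(policy)
        return None if status is Tristate.UNKNOWN else status is Tristate.POSITIVE
    if field == "mpo_or_p_positive":
        status = record.serology.mpo_or_p_status(policy)
        return None if status is Tristate.UNKNOWN else status is Tristate.POSITIVE
    if field == "eosinophil_count_ge_1":
        if record.eosinophil_count is None:
            return None
        return record.eosinophil_count >= 1.0
    value = getattr(record, field)
    if isinstance(value, HistologyFinding):
        if value is HistologyFinding.NO_BIOPSY:
            return None
        return value is HistologyFinding.PRESENT
    return bool(value)


def score_subtype_2022(
    record: PatientRecord,
    subtype: str,
    config: Optional[CriteriaConfig2022] = None,
) -> CriterionScore:
    """Apply one 2022 ACR/EULAR instrument to a record.

    Raises :class:`EntryConditionError` unless a vasculitis diagnosis has
    been established (the instruments classify, they do not diagnose).
    """
    if not record.vasculitis_diagnosis_established:
        raise EntryConditionError(
            f"patient {record.patient_id!r}: the 2022 ACR/EULAR criteria apply "
            "only after a small/medium-vessel vasculitis diagnosis is established"
        )
    config = config or default_config()
    if subtype not in config.subtypes:
        raise ValueError(f"unknown subtype {subtype!r}")
    spec = config.subtypes[subtype]
    contributions = []
    total = 0
    for item in spec["items"]:
        status = _item_status(record, item["field"], config.anca_precedence)
        if status is None:
            contributions.append(
                ItemContribution(
                    item_id=item["item_id"], fired=False, points=0,
                    note="unknown-input",
                )
            )
        elif status:
            total += item["weight"]
            contributions.append(
                ItemContribution(item_id=item["item_id"], fired=True,
                                 points=item["weight"])
            )
        else:
            contributions.append(
                ItemContribution(item_id=item["item_id"], fired=False, points=0)
            )
    threshold = spec["threshold"]
    return CriterionScore(
        subtype=SubtypeLabel(subtype),
        contributions=tuple(contributions),
        total=total,
        threshold=threshold,
        met=total >= threshold,
    )


def score_gpa_2022(record: PatientRecord, config=None) -> CriterionScore:
    """2022 ACR/EULAR GPA score (threshold 5)."""
    return score_subtype_2022(record, "GPA", config)


def score_mpa_2022(record: PatientRecord, config=None) -> CriterionScore:
    """2022 ACR/EULAR MPA score (threshold 5)."""
    return score_subtype_2022(record, "MPA", config)


def score_egpa_2022(record: PatientRecord, config=None) -> CriterionScore:
    """2022 ACR/EULAR EGPA score (threshold 6)."""
    return score_subtype_2022(record, "EGPA", config)


def classify_acr_eular_2022(
    record: PatientRecord, config: Optional[CriteriaConfig2022] = None
) -> ClassificationResult:
    """Multi-label classification under the 2022 ACR/EULAR criteria.

    Labels every subtype whose score is met; a patient meeting no score is
    labelled ``UNCLASSIFIED``.  Because the criteria specify no sequence,
    the label set may contain more than one subtype.
    """
    scores = {s: score_subtype_2022(record, s, config) for s in SUBTYPES_2022}
    labels = frozenset(
        SubtypeLabel(s) for s, score in scores.items() if score.met
    ) or frozenset({SubtypeLabel.UNCLASSIFIED})
    audit = tuple(
        (f"score_{s.lower()}_2022",
         f"total={score.total} threshold={score.threshold} "
         f"{'met' if score.met else 'not_met'}")
        for s, score in scores.items()
    )
    return ClassificationResult(
        patient_id=record.patient_id,
        system=System.ACR2022,
        labels=labels,
        audit=audit,
    )
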