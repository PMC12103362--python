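"""Shared domain types for ANCA-associated vasculitis (AAV) classification.

This module defines the patient-level feature model consumed by every
classification system in the package — the stepwise EMA algorithm, the
2022 ACR/EULAR weighted criteria, and the hybrid EMA-ACR/EULAR sequence —
together with the three-valued logic used for ANCA serology and renal
histology, so that "not tested" is never conflated with "tested negative".

Patient tables are plain CSV files, one row per patient, with the column
names listed in :data:`COLUMNS`; a machine-readable description of the
schema ships with the package (``data/patient_schema.json``).
"""

from __future__ import annotations

import enum
import json
from importlib import resources
from typing import Any, Iterable, Mapping, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field


class SchemaError(ValueError):
    """A patient row violates the table schema.

    Carries the offending column name so callers can point at the cell.
    """

    def __init__(self, column: str, message: str):
        self.column = column
        super().__init__(f"column {column!r}: {message}")


class CohortError(ValueError):
    """Cohort-level violation (e.g. duplicate patient identifiers)."""


class Tristate(str, enum.Enum):
    """Three-valued test result: positive / negative / unknown.

    ``UNKNOWN`` satisfies neither a positivity nor a negativity check.
    """

    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


class HistologyFinding(str, enum.Enum):
    """Biopsy finding with an explicit "no biopsy performed" state.

    ``NO_BIOPSY`` makes histology-gated classification routes unavailable
    rather than failed, and contributes nothing to weighted scores.
    """

    PRESENT = "present"
    ABSENT = "absent"
    NO_BIOPSY = "no_biopsy"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class SubtypeLabel(str, enum.Enum):
    """AAV subtype labels emitted by the classifiers.

    ``PAN`` (polyarteritis nodosa) is reachable only through the stepwise
    algorithms' final step, never from the 2022 ACR/EULAR scores.
    """

    MPA = "MPA"
    GPA = "GPA"
    EGPA = "EGPA"
    PAN = "PAN"
    UNCLASSIFIED = "UNCLASSIFIED"


class System(str, enum.Enum):
    """The three classification systems compared by this package."""

    EMA = "EMA"
    ACR2022 = "ACR2022"
    HYBRID = "HYBRID"


#: How discordant ELISA / immunofluorescence ANCA results are combined.
#: ``elisa_first``: the antigen-specific ELISA overrides the IIF pattern
#: whenever the ELISA result is known; IIF is consulted only when the
#: ELISA is unknown.  ``either_positive``: a positive on either assay
#: makes the compound predicate positive.
ANCA_PRECEDENCE_POLICIES = ("elisa_first", "either_positive")


class AncaSerology(BaseModel):
    """ANCA serology: indirect immunofluorescence + antigen-specific ELISA.

    The classifiers never consume the four raw assays directly; they use
    the two compound predicates ``pr3_or_c`` (PR3-ANCA or c-ANCA) and
    ``mpo_or_p`` (MPO-ANCA or p-ANCA), resolved under a configurable
    precedence policy (see :data:`ANCA_PRECEDENCE_POLICIES`).
    """

    model_config = ConfigDict(validate_assignment=True)

    iif_c_anca: Tristate = Tristate.UNKNOWN
    iif_p_anca: Tristate = Tristate.UNKNOWN
    elisa_pr3: Tristate = Tristate.UNKNOWN
    elisa_mpo: Tristate = Tristate.UNKNOWN

    @staticmethod
    def _compound(elisa: Tristate, iif: Tristate, policy: str) -> Tristate:
        if policy not in ANCA_PRECEDENCE_POLICIES:
            raise ValueError(f"unknown anca_precedence policy {policy!r}")
        if policy == "either_positive":
            if Tristate.POSITIVE in (elisa, iif):
                return Tristate.POSITIVE
            if Tristate.NEGATIVE in (elisa, iif):
                return Tristate.NEGATIVE
            return Tristate.UNKNOWN
        # elisa_first: a known ELISA result is authoritative
        if elisa is not Tristate.UNKNOWN:
            return elisa
        return iif

    def pr3_or_c_status(self, policy: str = "elisa_first") -> Tristate:
        """Compound PR3-ANCA (or c-ANCA) status under the given policy."""
        return self._compound(self.elisa_pr3, self.iif_c_anca, policy)

    def mpo_or_p_status(self, policy: str = "elisa_first") -> Tristate:
        """Compound MPO-ANCA (or p-ANCA) status under the given policy."""
        return self._compound(self.elisa_mpo, self.iif_p_anca, policy)

    def pr3_or_c_positive(self, policy: str = "elisa_first") -> bool:
        return self.pr3_or_c_status(policy) is Tristate.POSITIVE

    def mpo_or_p_positive(self, policy: str = "elisa_first") -> bool:
        return self.mpo_or_p_status(policy) is Tristate.POSITIVE

    def any_positive(self, policy: str = "elisa_first") -> bool:
        """ANCA positivity by any route (PR3/c or MPO/p)."""
        return self.pr3_or_c_positive(policy) or self.mpo_or_p_positive(policy)


#: Boolean clinical items (judged from history/exam/urinalysis).
CLINICAL_FLAGS = (
    "nasal_involvement",
    "cartilaginous_involvement",
    "hearing_loss",
    "obstructive_airway_disease",
    "nasal_polyps",
    "mononeuritis_multiplex",
    "oral_inflammation",
    "hematuria",
    "rbc_casts_or_dysmorphic",
    "proteinuria_2plus",
    "hematuria_2plus",
    "non_fixed_pulmonary_infiltrates",
)

#: Boolean imaging items (duration qualifiers pre-resolved by the abstractor).
IMAGING_FLAGS = (
    "pulmonary_nodules_mass_cavitation",
    "fixed_pulmonary_infiltrates_gt1mo",
    "bronchial_stenosis",
    "sinonasal_inflammation_or_mastoiditis_imaging",
    "paranasal_sinus_abnormality",
    "lung_fibrosis_or_ild",
    "retro_orbital_mass",
    "subglottic_stenosis",
    "saddle_nose",
    "chronic_sinusitis_otitis_mastoiditis_gt3mo",
    "abnormal_chest_radiograph",
)

#: Three-valued histology items.
HISTOLOGY_FLAGS = (
    "granulomatous_inflammation",
    "pauci_immune_gn",
    "eosinophil_predominant_extravascular_inflammation",
    "small_vessel_vasculitis_no_granuloma",
    "medium_vessel_necrotizing_arteritis",
)

SEROLOGY_FIELDS = ("iif_c_anca", "iif_p_anca", "elisa_pr3", "elisa_mpo")

BOOLEAN_FLAGS = CLINICAL_FLAGS + IMAGING_FLAGS + (
    "angiography_typical_pan",
    "vasculitis_diagnosis_established",
)


class PatientRecord(BaseModel):
    """One patient's classification-relevant features (single snapshot).

    Unstated boolean flags default to ``False``, serology and numeric labs
    to unknown, and histology to ``no_biopsy``; the defaulting policy is
    applied (and can be logged) by :func:`validate_record`.
    """

    model_config = ConfigDict(validate_assignment=True)

    patient_id: str
    age_years: Optional[float] = Field(default=None, ge=0)
    sex: Sex = Sex.UNKNOWN
    serology: AncaSerology = Field(default_factory=AncaSerology)

    #: blood eosinophil count, x10^9/L; None = not measured
    eosinophil_count: Optional[float] = Field(default=None, ge=0)
    #: blood eosinophils as % of leukocytes; None = not measured
    eosinophilia_pct: Optional[float] = Field(default=None, ge=0, le=100)

    # clinical flags
    nasal_involvement: bool = False
    cartilaginous_involvement: bool = False
    hearing_loss: bool = False
    obstructive_airway_disease: bool = False
    nasal_polyps: bool = False
    mononeuritis_multiplex: bool = False
    oral_inflammation: bool = False
    hematuria: bool = False
    rbc_casts_or_dysmorphic: bool = False
    proteinuria_2plus: bool = False
    hematuria_2plus: bool = False
    non_fixed_pulmonary_infiltrates: bool = False
    systemic_vasculitis_organs: int = Field(default=0, ge=0)

    # imaging flags
    pulmonary_nodules_mass_cavitation: bool = False
    fixed_pulmonary_infiltrates_gt1mo: bool = False
    bronchial_stenosis: bool = False
    sinonasal_inflammation_or_mastoiditis_imaging: bool = False
    paranasal_sinus_abnormality: bool = False
    lung_fibrosis_or_ild: bool = False
    retro_orbital_mass: bool = False
    subglottic_stenosis: bool = False
    saddle_nose: bool = False
    chronic_sinusitis_otitis_mastoiditis_gt3mo: bool = False
    abnormal_chest_radiograph: bool = False

    # histology
    granulomatous_inflammation: HistologyFinding = HistologyFinding.NO_BIOPSY
    pauci_immune_gn: HistologyFinding = HistologyFinding.NO_BIOPSY
    eosinophil_predominant_extravascular_inflammation: HistologyFinding = (
        HistologyFinding.NO_BIOPSY
    )
    small_vessel_vasculitis_no_granuloma: HistologyFinding = HistologyFinding.NO_BIOPSY
    medium_vessel_necrotizing_arteritis: HistologyFinding = HistologyFinding.NO_BIOPSY

    angiography_typical_pan: bool = False

    #: entry condition for the 2022 ACR/EULAR scores (classification, not
    #: diagnostic, instruments): a small/medium-vessel vasculitis diagnosis
    #: has been established before scoring.
    vasculitis_diagnosis_established: bool = False


class ClassificationResult(BaseModel):
    """Labels assigned to one patient by one system, with an audit trail.

    The stepwise systems (EMA, HYBRID) always emit exactly one label; the
    2022 ACR/EULAR scores may emit several (duplicate classification) and
    represent "no score met" as ``{UNCLASSIFIED}``.
    """

    patient_id: str
    system: System
    labels: frozenset[SubtypeLabel]
    audit: tuple[tuple[str, str], ...]

    def single_label(self) -> SubtypeLabel:
        """The unique label; error if the system emitted several."""
        if len(self.labels) != 1:
            raise ValueError(
                f"{self.system.value} result for {self.patient_id} has "
                f"{len(self.labels)} labels"
            )
        return next(iter(self.labels))


#: CSV column order for patient tables.
COLUMNS: tuple[str, ...] = (
    ("patient_id", "age_years", "sex")
    + SEROLOGY_FIELDS
    + ("eosinophil_count", "eosinophilia_pct")
    + CLINICAL_FLAGS
    + ("systemic_vasculitis_organs",)
    + IMAGING_FLAGS
    + HISTOLOGY_FLAGS
    + ("angiography_typical_pan", "vasculitis_diagnosis_established")
)

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def _parse_bool(column: str, value: Any) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise SchemaError(column, f"cannot interpret {value!r} as a boolean")


def _parse_tristate(column: str, value: Any) -> Tristate:
    text = str(value).strip().lower()
    if text == "":
        return Tristate.UNKNOWN
    try:
        return Tristate(text)
    except ValueError:
        raise SchemaError(column, f"expected positive/negative/unknown, got {value!r}")


def _parse_histology(column: str, value: Any) -> HistologyFinding:
    text = str(value).strip().lower()
    if text == "":
        return HistologyFinding.NO_BIOPSY
    try:
        return HistologyFinding(text)
    except ValueError:
        raise SchemaError(column, f"expected present/absent/no_biopsy, got {value!r}")


def _parse_optional_float(column: str, value: Any) -> Optional[float]:
    if value is None:
        return None
    text = str(value).strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise SchemaError(column, f"cannot interpret {value!r} as a number")


def validate_record(raw_row: Mapping[str, Any]) -> PatientRecord:
    """Validate one raw CSV row into a :class:`PatientRecord`.

    Defaulting policy: absent/empty boolean columns become ``False``,
    serology becomes ``unknown``, histology becomes ``no_biopsy``, and
    numeric labs become "not measured".  Unrecognised columns and
    out-of-range numerics raise :class:`SchemaError` naming the column.
    """
    if "patient_id" not in raw_row or str(raw_row["patient_id"]).strip() == "":
        raise SchemaError("patient_id", "missing or empty")

    known = set(COLUMNS)
    for column in raw_row:
        if column not in known:
            raise SchemaError(column, "not a recognised patient-table column")

    kwargs: dict[str, Any] = {"patient_id": str(raw_row["patient_id"]).strip()}

    if "sex" in raw_row:
        text = str(raw_row["sex"]).strip().lower()
        if text == "":
            kwargs["sex"] = Sex.UNKNOWN
        else:
            try:
                kwargs["sex"] = Sex(text)
            except ValueError:
                raise SchemaError("sex", f"expected male/female/unknown, got {text!r}")

    for column in ("age_years", "eosinophil_count", "eosinophilia_pct"):
        if column in raw_row:
            kwargs[column] = _parse_optional_float(column, raw_row[column])

    if "systemic_vasculitis_organs" in raw_row:
        text = str(raw_row["systemic_vasculitis_organs"]).strip()
        if text != "":
            try:
                kwargs["systemic_vasculitis_organs"] = int(float(text))
            except ValueError:
                raise SchemaError(
                    "systemic_vasculitis_organs",
                    f"cannot interpret {text!r} as an integer",
                )

    serology_kwargs = {}
    for column in SEROLOGY_FIELDS:
        if column in raw_row:
            serology_kwargs[column] = _parse_tristate(column, raw_row[column])
    kwargs["serology"] = AncaSerology(**serology_kwargs)

    for column in BOOLEAN_FLAGS:
        if column in raw_row:
            kwargs[column] = _parse_bool(column, raw_row[column])

    for column in HISTOLOGY_FLAGS:
        if column in raw_row:
            kwargs[column] = _parse_histology(column, raw_row[column])

    try:
        return PatientRecord(**kwargs)
    except Exception as exc:  # pydantic range violations -> named column
        message = str(exc)
        for column in ("age_years", "eosinophil_count", "eosinophilia_pct",
                       "systemic_vasculitis_organs"):
            if column in message:
                raise SchemaError(column, "out of range") from exc
        raise


def record_to_row(record: PatientRecord) -> dict[str, str]:
    """Serialize a record to a flat CSV row (inverse of :func:`validate_record`).

    Booleans become ``true``/``false``; unknown numerics and serology
    become empty strings; histology keeps its three-valued string.
    """
    row: dict[str, str] = {}
    for column in COLUMNS:
        if column in SEROLOGY_FIELDS:
            value = getattr(record.serology, column)
            row[column] = "" if value is Tristate.UNKNOWN else value.value
        elif column in HISTOLOGY_FLAGS:
            row[column] = getattr(record, column).value
        elif column in BOOLEAN_FLAGS:
            row[column] = "true" if getattr(record, column) else "false"
        elif column == "sex":
            row[column] = record.sex.value
        elif column == "systemic_vasculitis_organs":
            row[column] = str(record.systemic_vasculitis_organs)
        elif column == "patient_id":
            row[column] = record.patient_id
        else:  # optional numerics
            value = getattr(record, column)
            row[column] = "" if value is None else repr(value)
    return row


def load_cohort(path) -> list[PatientRecord]:
    """Read a patient-table CSV into validated records.

    Raises :class:`CohortError` on duplicate patient ids and
    :class:`SchemaError` on malformed cells.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = [validate_record(row) for row in frame.to_dict(orient="records")]
    seen: set[str] = set()
    for record in records:
        if record.patient_id in seen:
            raise CohortError(f"duplicate patient_id {record.patient_id!r}")
        seen.add(record.patient_id)
    return records


def save_cohort(records: Iterable[PatientRecord], path) -> None:
    """Write records to CSV with the canonical column order."""
    rows = [record_to_row(r) for r in records]
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    frame.to_csv(path, index=False)


def load_schema() -> dict:
    """The bundled machine-readable description of the patient table."""
    text = resources.files("aav_classify.data").joinpath("patient_schema.json").read_text()
    return json.loads(text)
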