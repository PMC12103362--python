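"""Pre-2022 building blocks used by the stepwise EMA algorithm.

Covers the 1990 ACR criteria for GPA (2-of-4) and EGPA (4-of-6), the
Lanham EGPA criteria (asthma + eosinophilia > 1.5 x10^9/L + vasculitis in
at least two extrapulmonary organs), the EMA surrogate-marker lists for
GPA and for renal vasculitis, and Chapel Hill (CHCC) histology
compatibility checks.

All cardinality rules (">= k of n items") are driven by a bundled JSON
config (``data/legacy_criteria.json``); each named item resolves to a
predicate over :class:`~aav_classify.core.PatientRecord`.  Items with
unknown inputs (no biopsy, unmeasured eosinophils) simply do not count
toward the cardinality.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Callable, Optional

from pydantic import BaseModel

from .core import HistologyFinding, PatientRecord


class LegacyVerdict(BaseModel):
    """Outcome of one legacy rule: which items held and whether it passed."""

    rule_id: str
    satisfied: bool
    satisfied_items: tuple[str, ...]
    note: Optional[str] = None


class LegacyConfig(BaseModel):
    version: str
    rules: dict[str, dict]

    @classmethod
    def load_default(cls) -> "LegacyConfig":
        text = (
            resources.files("aav_classify.data")
            .joinpath("legacy_criteria.json")
            .read_text()
        )
        return cls(**json.loads(text))

    @classmethod
    def load(cls, path) -> "LegacyConfig":
        with open(path) as handle:
            return cls(**json.load(handle))


_DEFAULT_CONFIG: Optional[LegacyConfig] = None


def default_config() -> LegacyConfig:
    global _DEFAULT_CONFIG
    if _DEFAULT_CONFIG is None:
        _DEFAULT_CONFIG = LegacyConfig.load_default()
    return _DEFAULT_CONFIG


def _histology_present(record: PatientRecord, field: str) -> bool:
    return getattr(record, field) is HistologyFinding.PRESENT


#: item_id -> predicate over a record; unknown inputs evaluate False
ITEM_PREDICATES: dict[str, Callable[[PatientRecord], bool]] = {
    # 1990 ACR GPA
    "nasal_or_oral_inflammation": lambda r: r.nasal_involvement or r.oral_inflammation,
    "abnormal_chest_radiograph": lambda r: r.abnormal_chest_radiograph,
    "active_urinary_sediment": lambda r: r.hematuria or r.rbc_casts_or_dysmorphic,
    "granulomatous_inflammation_on_biopsy": lambda r: _histology_present(
        r, "granulomatous_inflammation"
    ),
    # 1990 ACR EGPA
    "asthma": lambda r: r.obstructive_airway_disease,
    "eosinophilia_gt_10pct": lambda r: (
        r.eosinophilia_pct is not None and r.eosinophilia_pct > 10
    ),
    "mono_or_polyneuropathy": lambda r: r.mononeuritis_multiplex,
    "non_fixed_pulmonary_infiltrates": lambda r: r.non_fixed_pulmonary_infiltrates,
    "paranasal_sinus_abnormality": lambda r: r.paranasal_sinus_abnormality,
    "extravascular_eosinophils_on_biopsy": lambda r: _histology_present(
        r, "eosinophil_predominant_extravascular_inflammation"
    ),
    # Lanham
    "eosinophil_count_gt_1_5e9_per_l": lambda r: (
        r.eosinophil_count is not None and r.eosinophil_count > 1.5
    ),
    "vasculitis_in_ge_2_extrapulmonary_organs": lambda r: (
        r.systemic_vasculitis_organs >= 2
    ),
    # GPA surrogate markers
    "fixed_pulmonary_infiltrates_gt1mo": lambda r: r.fixed_pulmonary_infiltrates_gt1mo,
    "pulmonary_nodules_mass_cavitation": lambda r: r.pulmonary_nodules_mass_cavitation,
    "bronchial_stenosis": lambda r: r.bronchial_stenosis,
    "bloody_nasal_discharge_crusting_or_ulceration": lambda r: r.nasal_involvement,
    "chronic_sinusitis_otitis_mastoiditis_gt3mo": lambda r: (
        r.chronic_sinusitis_otitis_mastoiditis_gt3mo
    ),
    "retro_orbital_mass": lambda r: r.retro_orbital_mass,
    "subglottic_stenosis": lambda r: r.subglottic_stenosis,
    "saddle_nose": lambda r: r.saddle_nose,
    # renal vasculitis surrogate
    "hematuria_with_rbc_casts_or_dysmorphic": lambda r: (
        r.hematuria and r.rbc_casts_or_dysmorphic
    ),
    "hematuria_2plus_with_proteinuria_2plus": lambda r: (
        r.hematuria_2plus and r.proteinuria_2plus
    ),
}


def evaluate_rule(
    record: PatientRecord, rule_id: str, config: Optional[LegacyConfig] = None
) -> LegacyVerdict:
    """Evaluate one cardinality rule from the legacy config."""
    config = config or default_config()
    if rule_id not in config.rules:
        raise ValueError(f"unknown legacy rule {rule_id!r}")
    rule = config.rules[rule_id]
    satisfied_items = tuple(
        item for item in rule["items"] if ITEM_PREDICATES[item](record)
    )
    return LegacyVerdict(
        rule_id=rule_id,
        satisfied=len(satisfied_items) >= rule["min_count"],
        satisfied_items=satisfied_items,
    )


def acr1990_gpa(record: PatientRecord, config=None) -> LegacyVerdict:
    """1990 ACR GPA criteria: at least 2 of 4 items."""
    return evaluate_rule(record, "ACR1990_GPA", config)


def acr1990_egpa(record: PatientRecord, config=None) -> LegacyVerdict:
    """1990 ACR EGPA criteria: at least 4 of 6 items."""
    return evaluate_rule(record, "ACR1990_EGPA", config)


def lanham_egpa(record: PatientRecord, config=None) -> LegacyVerdict:
    """Lanham EGPA criteria: all three of asthma, eosinophils > 1.5, >= 2 organs."""
    return evaluate_rule(record, "LANHAM", config)


def surrogate_gpa(record: PatientRecord, config=None) -> LegacyVerdict:
    """Any of the eight EMA surrogate markers for granulomatous (GPA) disease."""
    return evaluate_rule(record, "SURROGATE_GPA", config)


def surrogate_renal(record: PatientRecord, config=None) -> LegacyVerdict:
    """EMA surrogate for renal vasculitis: hematuria with red-cell casts /
    dysmorphic erythrocytes, or 2+ hematuria with 2+ proteinuria."""
    return evaluate_rule(record, "SURROGATE_RENAL", config)


_CHCC_RULE_IDS = {"GPA": "CHCC_GPA_HISTO", "MPA": "CHCC_MPA_HISTO", "PAN": "CHCC_PAN"}


def chcc_compatibility(record: PatientRecord, target: str) -> LegacyVerdict:
    """Histology (or, for PAN, angiography) compatibility with a CHCC entity.

    GPA requires granulomatous inflammation on biopsy; MPA requires
    small-vessel vasculitis without granulomas (and no granulomas found);
    PAN requires medium-vessel necrotizing arteritis or typical angiography.
    When the deciding histology was never biopsied the verdict is
    not-satisfied with a ``no_biopsy`` note: the route is unavailable,
    not failed.
    """
    if target not in _CHCC_RULE_IDS:
        raise ValueError(f"unknown CHCC target {target!r}")
    rule_id = _CHCC_RULE_IDS[target]
    if target == "GPA":
        finding = record.granulomatous_inflammation
        if finding is HistologyFinding.PRESENT:
            return LegacyVerdict(
                rule_id=rule_id, satisfied=True,
                satisfied_items=("granulomatous_inflammation",),
            )
        note = "no_biopsy" if finding is HistologyFinding.NO_BIOPSY else None
        return LegacyVerdict(rule_id=rule_id, satisfied=False,
                             satisfied_items=(), note=note)
    if target == "MPA":
        svv = record.small_vessel_vasculitis_no_granuloma
        granuloma = record.granulomatous_inflammation
        if svv is HistologyFinding.PRESENT and granuloma is not HistologyFinding.PRESENT:
            return LegacyVerdict(
                rule_id=rule_id, satisfied=True,
                satisfied_items=("small_vessel_vasculitis_no_granuloma",),
            )
        note = "no_biopsy" if svv is HistologyFinding.NO_BIOPSY else None
        return LegacyVerdict(rule_id=rule_id, satisfied=False,
                             satisfied_items=(), note=note)
    # PAN
    items = []
    if record.medium_vessel_necrotizing_arteritis is HistologyFinding.PRESENT:
        items.append("medium_vessel_necrotizing_arteritis")
    if record.angiography_typical_pan:
        items.append("angiography_typical_pan")
    if items:
        return LegacyVerdict(rule_id=rule_id, satisfied=True,
                             satisfied_items=tuple(items))
    note = (
        "no_biopsy"
        if record.medium_vessel_necrotizing_arteritis is HistologyFinding.NO_BIOPSY
        else None
    )
    return LegacyVerdict(rule_id=rule_id, satisfied=False,
                         satisfied_items=(), note=note)
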