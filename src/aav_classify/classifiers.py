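"""Stepwise single-label classification algorithms for AAV.

Two sequential algorithms are implemented:

* the EMA consensus algorithm, which assigns exactly one category per
  patient in a fixed order (EGPA -> GPA -> MPA -> PAN -> unclassifiable)
  using the 1990 ACR criteria, the Lanham criteria, CHCC histology
  definitions and surrogate markers; and

* the EMA-ACR/EULAR hybrid, which keeps the EMA step order but replaces
  the 1990 ACR instruments with the 2022 ACR/EULAR weighted scores,
  thereby guaranteeing a single label where the bare 2022 scores can
  assign several.

Each classification carries a replayable :class:`StepTrace` recording
which rules were evaluated at each step and which terminal fired.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel

from . import criteria_legacy as legacy
from .core import (
    ClassificationResult,
    CohortError,
    PatientRecord,
    SubtypeLabel,
    System,
)
from .criteria_2022 import (
    CriteriaConfig2022,
    classify_acr_eular_2022,
    score_egpa_2022,
    score_gpa_2022,
    score_mpa_2022,
)

EGPA_RULE_CHOICES = ("either", "acr1990", "lanham")
STEP3_POLICIES = ("ema_routes_only", "acr2022_score_only", "either")


class StepEntry(BaseModel):
    step: str
    rules: tuple[str, ...]
    outcome: str


class StepTrace(BaseModel):
    """Ordered record of the steps a sequential classifier evaluated."""

    entries: tuple[StepEntry, ...]
    terminal: SubtypeLabel

    def to_audit(self) -> tuple[tuple[str, str], ...]:
        audit = tuple(
            (f"{e.step}[{','.join(e.rules)}]", e.outcome) for e in self.entries
        )
        return audit + (("terminal", self.terminal.value),)


def _result(record: PatientRecord, system: System, trace: StepTrace) -> ClassificationResult:
    if trace.terminal is SubtypeLabel.PAN:
        warnings.warn(
            f"patient {record.patient_id!r} classified as PAN, which is outside "
            "the ANCA-associated vasculitides",
            stacklevel=3,
        )
    return ClassificationResult(
        patient_id=record.patient_id,
        system=system,
        labels=frozenset({trace.terminal}),
        audit=trace.to_audit(),
    )


def _anca_positive(record: PatientRecord, policy: str = "elisa_first") -> bool:
    return record.serology.any_positive(policy)


def classify_ema(
    record: PatientRecord,
    legacy_config: Optional[legacy.LegacyConfig] = None,
    egpa_rule: str = "either",
) -> ClassificationResult:
    """Classify one patient with the stepwise EMA algorithm.

    Steps, in order:

    1. EGPA — 1990 ACR EGPA criteria or Lanham criteria (``egpa_rule``
       selects which routes are admissible; default both).
    2. GPA — 1990 ACR GPA criteria, or CHCC-compatible histology
       (granulomas), or a GPA surrogate marker together with ANCA
       positivity.
    3. MPA — CHCC-compatible histology without granulomas, or a renal
       vasculitis surrogate with ANCA positivity; either route requires
       the absence of GPA surrogate markers.
    4. PAN — CHCC-compatible histology or typical angiography.

    Otherwise the patient is unclassifiable.
    """
    if egpa_rule not in EGPA_RULE_CHOICES:
        raise ValueError(f"egpa_rule must be one of {EGPA_RULE_CHOICES}")
    entries = []

    # step 1: EGPA
    rules, verdicts = [], []
    if egpa_rule in ("either", "acr1990"):
        rules.append("ACR1990_EGPA")
        verdicts.append(legacy.acr1990_egpa(record, legacy_config).satisfied)
    if egpa_rule in ("either", "lanham"):
        rules.append("LANHAM")
        verdicts.append(legacy.lanham_egpa(record, legacy_config).satisfied)
    hit = any(verdicts)
    entries.append(StepEntry(step="step1_egpa", rules=tuple(rules),
                             outcome="met" if hit else "not_met"))
    if hit:
        return _result(record, System.EMA,
                       StepTrace(entries=tuple(entries), terminal=SubtypeLabel.EGPA))

    # step 2: GPA
    acr_gpa = legacy.acr1990_gpa(record, legacy_config).satisfied
    chcc_gpa = legacy.chcc_compatibility(record, "GPA").satisfied
    surrogate = legacy.surrogate_gpa(record, legacy_config).satisfied
    gpa_hit = acr_gpa or chcc_gpa or (surrogate and _anca_positive(record))
    entries.append(StepEntry(
        step="step2_gpa",
        rules=("ACR1990_GPA", "CHCC_GPA_HISTO", "SURROGATE_GPA+ANCA"),
        outcome="met" if gpa_hit else "not_met",
    ))
    if gpa_hit:
        return _result(record, System.EMA,
                       StepTrace(entries=tuple(entries), terminal=SubtypeLabel.GPA))

    # step 3: MPA (blocked by any GPA surrogate marker)
    chcc_mpa = legacy.chcc_compatibility(record, "MPA").satisfied
    renal = legacy.surrogate_renal(record, legacy_config).satisfied
    mpa_hit = (not surrogate) and (chcc_mpa or (renal and _anca_positive(record)))
    entries.append(StepEntry(
        step="step3_mpa",
        rules=("CHCC_MPA_HISTO", "SURROGATE_RENAL+ANCA"),
        outcome="met" if mpa_hit else "not_met",
    ))
    if mpa_hit:
        return _result(record, System.EMA,
                       StepTrace(entries=tuple(entries), terminal=SubtypeLabel.MPA))

    # step 4: PAN
    pan_hit = legacy.chcc_compatibility(record, "PAN").satisfied
    entries.append(StepEntry(step="step4_pan", rules=("CHCC_PAN",),
                             outcome="met" if pan_hit else "not_met"))
    terminal = SubtypeLabel.PAN if pan_hit else SubtypeLabel.UNCLASSIFIED
    return _result(record, System.EMA,
                   StepTrace(entries=tuple(entries), terminal=terminal))


def classify_hybrid(
    record: PatientRecord,
    step3_policy: str = "either",
    config_2022: Optional[CriteriaConfig2022] = None,
    legacy_config: Optional[legacy.LegacyConfig] = None,
) -> ClassificationResult:
    """Classify one patient with the EMA-ACR/EULAR hybrid algorithm.

    The EMA step order is retained but the 1990 ACR instruments are
    replaced by the 2022 ACR/EULAR scores:

    1. EGPA — 2022 EGPA score met.
    2. GPA — 2022 GPA score met, or CHCC-compatible histology, or a GPA
       surrogate marker with ANCA positivity.
    3. MPA — controlled by ``step3_policy``: ``ema_routes_only`` keeps the
       EMA renal/histology routes unchanged, ``acr2022_score_only`` uses
       the 2022 MPA score, ``either`` (default) accepts both.
    4. PAN — as in the EMA algorithm.

    Always emits exactly one label, which resolves the duplicate
    classification possible under the bare 2022 scores.
    """
    if step3_policy not in STEP3_POLICIES:
        raise ValueError(f"step3_policy must be one of {STEP3_POLICIES}")
    entries = []

    egpa = score_egpa_2022(record, config_2022)  # also enforces entry condition
    entries.append(StepEntry(step="step1_egpa", rules=("ACR_EULAR_2022_EGPA",),
                             outcome="met" if egpa.met else "not_met"))
    if egpa.met:
        return _result(record, System.HYBRID,
                       StepTrace(entries=tuple(entries), terminal=SubtypeLabel.EGPA))

    gpa_score = score_gpa_2022(record, config_2022)
    chcc_gpa = legacy.chcc_compatibility(record, "GPA").satisfied
    surrogate = legacy.surrogate_gpa(record, legacy_config).satisfied
    gpa_hit = gpa_score.met or chcc_gpa or (surrogate and _anca_positive(record))
    entries.append(StepEntry(
        step="step2_gpa",
        rules=("ACR_EULAR_2022_GPA", "CHCC_GPA_HISTO", "SURROGATE_GPA+ANCA"),
        outcome="met" if gpa_hit else "not_met",
    ))
    if gpa_hit:
        return _result(record, System.HYBRID,
                       StepTrace(entries=tuple(entries), terminal=SubtypeLabel.GPA))

    ema_route = False
    score_route = False
    rules: list[str] = []
    if step3_policy in ("ema_routes_only", "either"):
        chcc_mpa = legacy.chcc_compatibility(record, "MPA").satisfied
        renal = legacy.surrogate_renal(record, legacy_config).satisfied
        ema_route = (not surrogate) and (
            chcc_mpa or (renal and _anca_positive(record))
        )
        rules += ["CHCC_MPA_HISTO", "SURROGATE_RENAL+ANCA"]
    if step3_policy in ("acr2022_score_only", "either"):
        score_route = score_mpa_2022(record, config_2022).met
        rules.append("ACR_EULAR_2022_MPA")
    mpa_hit = ema_route or score_route
    entries.append(StepEntry(step="step3_mpa", rules=tuple(rules),
                             outcome="met" if mpa_hit else "not_met"))
    if mpa_hit:
        return _result(record, System.HYBRID,
                       StepTrace(entries=tuple(entries), terminal=SubtypeLabel.MPA))

    pan_hit = legacy.chcc_compatibility(record, "PAN").satisfied
    entries.append(StepEntry(step="step4_pan", rules=("CHCC_PAN",),
                             outcome="met" if pan_hit else "not_met"))
    terminal = SubtypeLabel.PAN if pan_hit else SubtypeLabel.UNCLASSIFIED
    return _result(record, System.HYBRID,
                   StepTrace(entries=tuple(entries), terminal=terminal))


def classify_record(record: PatientRecord, system: System, **options) -> ClassificationResult:
    """Dispatch a single record to the requested classification system."""
    if system is System.EMA:
        return classify_ema(record, **options)
    if system is System.ACR2022:
        return classify_acr_eular_2022(record, **options)
    if system is System.HYBRID:
        return classify_hybrid(record, **options)
    raise ValueError(f"unknown system {system!r}")


def classify_cohort(
    records: Sequence[PatientRecord], system: System, **options
) -> tuple[list[ClassificationResult], pd.DataFrame]:
    """Classify a cohort and tabulate label frequencies.

    Returns the per-patient results and a summary frame with one row per
    label (count and percentage of cohort size).  Under ACR2022 a patient
    carrying several labels is counted once per label, and the number of
    multi-label patients is exposed in the frame's ``attrs`` under
    ``n_multi_label``.
    """
    seen: set[str] = set()
    for record in records:
        if record.patient_id in seen:
            raise CohortError(f"duplicate patient_id {record.patient_id!r}")
        seen.add(record.patient_id)

    results = [classify_record(record, system, **options) for record in records]
    n = len(records)
    counts = {label: 0 for label in SubtypeLabel}
    n_multi = 0
    for result in results:
        if len(result.labels) > 1:
            n_multi += 1
        for label in result.labels:
            counts[label] += 1
    summary = pd.DataFrame(
        {
            "label": [label.value for label in SubtypeLabel],
            "count": [counts[label] for label in SubtypeLabel],
            "percent": [
                round(100.0 * counts[label] / n, 1) if n else 0.0
                for label in SubtypeLabel
            ],
        }
    )
    summary.attrs["n_patients"] = n
    summary.attrs["n_multi_label"] = n_multi
    return results, summary
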