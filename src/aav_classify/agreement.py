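"""Agreement and reclassification statistics between classification systems.

Implements the 2x2 cross-classification table for a target subtype,
Cohen's kappa with an asymptotic standard error and confidence interval,
simple percent agreement, and the categorical Net Reclassification Index

    NRI = (n1 - n2) / N1 - (n3 - n4) / N2

where a reference system splits the cohort into target (N1) and
non-target (N2) patients and n1..n4 count patients the "new" system moves
toward (n1, n4) or away from (n2, n3) the reference relative to the "old"
system.

Kappa uncertainty uses the large-sample Fleiss-Cohen-Everitt variance for
the confidence interval and the null-hypothesis variance for the two-sided
z-test of kappa = 0.  The NRI standard error is the categorical form
sqrt((n1 + n2) / N1^2 + (n3 + n4) / N2^2), again with a two-sided z-test.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Union

from pydantic import BaseModel
from scipy.stats import norm

from .core import SubtypeLabel

DUAL_HANDLING_POLICIES = ("target_only_if_pure", "target_if_member")

LabelSet = Union[SubtypeLabel, str, frozenset, set]


class UndefinedNRIError(ValueError):
    """The reference partition has an empty side, so the NRI is undefined."""


class AgreementTable(BaseModel):
    """2x2 cross-classification for one target label.

    ``a``: both systems assign the target; ``b``: system 1 only;
    ``c``: system 2 only; ``d``: neither.
    """

    target_label: str
    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def model_post_init(self, __context) -> None:
        for cell in ("a", "b", "c", "d"):
            if getattr(self, cell) < 0:
                raise ValueError(f"cell {cell} must be non-negative")


class KappaResult(BaseModel):
    """Cohen's kappa with asymptotic SE, 95% CI and z-test p-value."""

    kappa: float
    se: float
    ci_lower: float
    ci_upper: float
    p_value: float
    po: float
    pe: float
    note: Optional[str] = None

    def ci_display(self) -> tuple[float, float]:
        """CI with the lower bound floored at 0 for reporting."""
        return (max(0.0, self.ci_lower), self.ci_upper)


class NriResult(BaseModel):
    """Categorical NRI with its component counts, SE, 95% CI and p-value."""

    N1: int
    N2: int
    n1: int
    n2: int
    n3: int
    n4: int
    nri: float
    se: float
    ci_lower: float
    ci_upper: float
    p_value: float


def _as_label_set(value: LabelSet) -> frozenset:
    if isinstance(value, (set, frozenset)):
        return frozenset(
            v.value if isinstance(v, SubtypeLabel) else str(v) for v in value
        )
    if isinstance(value, SubtypeLabel):
        return frozenset({value.value})
    return frozenset({str(value)})


def _is_target(labels: LabelSet, target: str, dual_handling: str) -> bool:
    label_set = _as_label_set(labels)
    if dual_handling == "target_only_if_pure":
        return label_set == frozenset({target})
    if dual_handling == "target_if_member":
        return target in label_set
    raise ValueError(f"dual_handling must be one of {DUAL_HANDLING_POLICIES}")


def cross_tab(
    labels_sys1: Mapping[str, LabelSet],
    labels_sys2: Mapping[str, LabelSet],
    target_label: Union[SubtypeLabel, str],
    dual_handling: str = "target_only_if_pure",
) -> AgreementTable:
    """Cross-classify two systems' labels against a target subtype.

    ``dual_handling`` decides whether a multi-label patient (possible under
    the 2022 scores) counts as the target: ``target_only_if_pure`` (default)
    requires the label set to be exactly the target, so a dual MPA+GPA
    patient sits in neither pure marginal; ``target_if_member`` accepts
    membership.
    """
    if set(labels_sys1) != set(labels_sys2):
        raise ValueError("the two systems cover different patient sets")
    target = target_label.value if isinstance(target_label, SubtypeLabel) else str(target_label)
    a = b = c = d = 0
    for patient_id in labels_sys1:
        t1 = _is_target(labels_sys1[patient_id], target, dual_handling)
        t2 = _is_target(labels_sys2[patient_id], target, dual_handling)
        if t1 and t2:
            a += 1
        elif t1:
            b += 1
        elif t2:
            c += 1
        else:
            d += 1
    return AgreementTable(target_label=target, a=a, b=b, c=c, d=d)


def table_from_marginals(
    target_label: str, n: int, sys1_target: int, sys2_target: int, both: int
) -> AgreementTable:
    """Reconstruct a 2x2 table from its marginals and the agreement cell.

    Convenience for published summaries that print only "system 1 found X,
    system 2 found Y, both found Z of N patients".
    """
    a = both
    b = sys1_target - both
    c = sys2_target - both
    d = n - a - b - c
    return AgreementTable(target_label=target_label, a=a, b=b, c=c, d=d)


def cohen_kappa(table: AgreementTable) -> KappaResult:
    """Cohen's kappa for a 2x2 agreement table.

    kappa = (po - pe) / (1 - pe) with po the observed agreement and pe the
    chance agreement from the marginals.  A degenerate table with pe = 1
    (both systems constant) is reported as kappa = 1 with a note.
    """
    n = table.n
    if n == 0:
        raise ValueError("empty agreement table")
    p = [[table.a / n, table.b / n], [table.c / n, table.d / n]]
    row = [p[0][0] + p[0][1], p[1][0] + p[1][1]]
    col = [p[0][0] + p[1][0], p[0][1] + p[1][1]]
    po = p[0][0] + p[1][1]
    pe = row[0] * col[0] + row[1] * col[1]
    if math.isclose(pe, 1.0):
        return KappaResult(kappa=1.0, se=0.0, ci_lower=1.0, ci_upper=1.0,
                           p_value=1.0, po=po, pe=pe, note="degenerate-table")
    kappa = (po - pe) / (1 - pe)

    # large-sample variance (Fleiss, Cohen & Everitt) for the CI
    a_term = sum(
        p[i][i] * (1 - (row[i] + col[i]) * (1 - kappa)) ** 2 for i in range(2)
    )
    b_term = (1 - kappa) ** 2 * sum(
        p[i][j] * (col[i] + row[j]) ** 2
        for i in range(2) for j in range(2) if i != j
    )
    c_term = (kappa - pe * (1 - kappa)) ** 2
    var = (a_term + b_term - c_term) / ((1 - pe) ** 2 * n)
    se = math.sqrt(max(var, 0.0))

    # null-hypothesis variance for the z-test of kappa = 0
    var0 = (
        pe + pe ** 2 - sum(row[i] * col[i] * (row[i] + col[i]) for i in range(2))
    ) / ((1 - pe) ** 2 * n)
    se0 = math.sqrt(max(var0, 0.0))
    if se0 > 0:
        z = kappa / se0
        p_value = float(2 * norm.sf(abs(z)))
        p_value = max(p_value, 1e-300)
    else:
        p_value = 1.0

    z975 = float(norm.ppf(0.975))
    ci_lower = max(-1.0, kappa - z975 * se)
    ci_upper = min(1.0, kappa + z975 * se)
    return KappaResult(kappa=kappa, se=se, ci_lower=ci_lower, ci_upper=ci_upper,
                       p_value=p_value, po=po, pe=pe)


def percent_agreement(table: AgreementTable, direction: str = "system1") -> float:
    """Share of one system's target patients confirmed by the other, in %.

    ``system1``: a / (a + b); ``system2``: a / (a + c).  Reported to one
    decimal place.
    """
    if direction == "system1":
        denom = table.a + table.b
    elif direction == "system2":
        denom = table.a + table.c
    else:
        raise ValueError("direction must be 'system1' or 'system2'")
    if denom == 0:
        raise ZeroDivisionError(f"no {direction} patients carry the target label")
    return round(100.0 * table.a / denom, 1)


def compute_nri(
    reference_labels: Mapping[str, LabelSet],
    old_labels: Mapping[str, LabelSet],
    new_labels: Mapping[str, LabelSet],
    target_label: Union[SubtypeLabel, str],
    dual_handling: str = "target_only_if_pure",
) -> NriResult:
    """Categorical NRI of a new system over an old one, given a reference.

    The reference system dichotomises patients into target (N1) and
    non-target (N2).  Within N1, n1 counts patients the old system called
    non-target but the new system calls target, and n2 the reverse; within
    N2, n3 counts patients newly called target and n4 patients newly
    called non-target.  NRI = (n1 - n2)/N1 - (n3 - n4)/N2.
    """
    if not (set(reference_labels) == set(old_labels) == set(new_labels)):
        raise ValueError("the three label vectors cover different patient sets")
    target = target_label.value if isinstance(target_label, SubtypeLabel) else str(target_label)

    N1 = N2 = n1 = n2 = n3 = n4 = 0
    for patient_id in reference_labels:
        ref = _is_target(reference_labels[patient_id], target, dual_handling)
        old = _is_target(old_labels[patient_id], target, dual_handling)
        new = _is_target(new_labels[patient_id], target, dual_handling)
        if ref:
            N1 += 1
            if not old and new:
                n1 += 1
            elif old and not new:
                n2 += 1
        else:
            N2 += 1
            if not old and new:
                n3 += 1
            elif old and not new:
                n4 += 1

    if N1 == 0 or N2 == 0:
        raise UndefinedNRIError(
            f"reference partition for {target!r} is one-sided (N1={N1}, N2={N2})"
        )
    nri = (n1 - n2) / N1 - (n3 - n4) / N2
    se = math.sqrt((n1 + n2) / N1 ** 2 + (n3 + n4) / N2 ** 2)
    if se > 0:
        z = nri / se
        p_value = float(2 * norm.sf(abs(z)))
        p_value = max(p_value, 1e-300)
    else:
        p_value = 1.0
    z975 = float(norm.ppf(0.975))
    return NriResult(N1=N1, N2=N2, n1=n1, n2=n2, n3=n3, n4=n4, nri=nri, se=se,
                     ci_lower=nri - z975 * se, ci_upper=nri + z975 * se,
                     p_value=p_value)


def labels_of(results: Iterable) -> dict[str, frozenset]:
    """patient_id -> label set, from an iterable of ClassificationResult."""
    return {r.patient_id: _as_label_set(r.labels) for r in results}
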