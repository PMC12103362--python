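"""Cross-tabulation, Cohen's kappa, percent agreement, and categorical NRI."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from aav_classify import (
    AgreementTable,
    UndefinedNRIError,
    cohen_kappa,
    compute_nri,
    cross_tab,
    percent_agreement,
    table_from_marginals,
)

# 2x2 tables reconstructed from published cohort marginals (N = 179):
# for MPA the two systems found 136 and 145 patients, 121 in common;
# for GPA 14 and 14 with 4 in common.
MPA_TABLE = table_from_marginals("MPA", 179, 136, 145, 121)
GPA_TABLE = table_from_marginals("GPA", 179, 14, 14, 4)


def test_marginal_reconstruction():
    assert (MPA_TABLE.a, MPA_TABLE.b, MPA_TABLE.c, MPA_TABLE.d) == (121, 15, 24, 19)
    assert (GPA_TABLE.a, GPA_TABLE.b, GPA_TABLE.c, GPA_TABLE.d) == (4, 10, 10, 155)


@pytest.mark.parametrize(
    "table, kappa3, ci3, pmax",
    [
        (MPA_TABLE, 0.357, (0.196, 0.518), 0.001),
        (GPA_TABLE, 0.225, (0.000, 0.456), 0.005),
    ],
)
def test_kappa_worked_examples(table, kappa3, ci3, pmax):
    result = cohen_kappa(table)
    assert round(result.kappa, 3) == kappa3
    lo, hi = result.ci_display()
    assert round(lo, 3) == pytest.approx(ci3[0], abs=0.005)
    assert round(hi, 3) == pytest.approx(ci3[1], abs=0.005)
    assert result.p_value < pmax


def test_kappa_matches_statsmodels_reference():
    from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

    for table in (MPA_TABLE, GPA_TABLE, AgreementTable(target_label="x", a=7, b=2, c=9, d=30)):
        ours = cohen_kappa(table)
        ref = sm_kappa(np.array([[table.a, table.b], [table.c, table.d]]))
        assert ours.kappa == pytest.approx(ref.kappa, abs=1e-12)
        assert ours.se == pytest.approx(math.sqrt(ref.var_kappa), abs=1e-12)


def test_kappa_perfect_and_degenerate():
    perfect = AgreementTable(target_label="x", a=10, b=0, c=0, d=10)
    assert cohen_kappa(perfect).kappa == 1.0
    degenerate = AgreementTable(target_label="x", a=10, b=0, c=0, d=0)
    result = cohen_kappa(degenerate)
    assert result.kappa == 1.0 and result.note == "degenerate-table"
    with pytest.raises(ValueError):
        cohen_kappa(AgreementTable(target_label="x", a=0, b=0, c=0, d=0))


@pytest.mark.parametrize(
    "a, b, expected",
    [(121, 15, 89.0), (15, 14, 51.7), (10, 4, 71.4), (0, 5, 0.0)],
)
def test_percent_agreement(a, b, expected):
    table = AgreementTable(target_label="x", a=a, b=b, c=0, d=0)
    assert percent_agreement(table, "system1") == expected


def test_percent_agreement_zero_marginal():
    with pytest.raises(ZeroDivisionError):
        percent_agreement(AgreementTable(target_label="x", a=0, b=0, c=3, d=1))


def test_cross_tab_dual_handling():
    sys1 = {"p1": {"MPA"}, "p2": {"MPA", "GPA"}, "p3": {"GPA"}}
    sys2 = {"p1": {"MPA"}, "p2": {"MPA"}, "p3": {"UNCLASSIFIED"}}
    pure = cross_tab(sys1, sys2, "MPA", "target_only_if_pure")
    assert (pure.a, pure.b, pure.c, pure.d) == (1, 0, 1, 1)
    member = cross_tab(sys1, sys2, "MPA", "target_if_member")
    assert (member.a, member.b, member.c, member.d) == (2, 0, 0, 1)
    with pytest.raises(ValueError):
        cross_tab(sys1, {"p1": {"MPA"}}, "MPA")


def test_identical_assignments_agree_perfectly():
    labels = {f"p{i}": {"MPA" if i % 2 else "GPA"} for i in range(10)}
    table = cross_tab(labels, labels, "MPA")
    assert table.b == table.c == 0
    assert cohen_kappa(table).kappa == 1.0


# --- NRI --------------------------------------------------------------------


def _nri_oracle(reference, old, new, target):
    """Set-algebra re-derivation of the categorical NRI."""
    ids = set(reference)
    in_target = lambda labels, pid: labels[pid] == target
    N1 = {p for p in ids if in_target(reference, p)}
    N2 = ids - N1
    up = {p for p in ids if not in_target(old, p) and in_target(new, p)}
    down = {p for p in ids if in_target(old, p) and not in_target(new, p)}
    return (len(N1 & up) - len(N1 & down)) / len(N1) - (
        (len(N2 & up) - len(N2 & down)) / len(N2)
    )


def test_nri_hand_worked_example():
    # N1 = 10 with n1 = 2, n2 = 1; N2 = 10 with n3 = 1, n4 = 2
    reference, old, new = {}, {}, {}
    for i in range(10):
        reference[f"t{i}"] = "MPA"
        old[f"t{i}"] = "MPA" if i >= 3 else ("UNCLASSIFIED" if i < 2 else "MPA")
        new[f"t{i}"] = "MPA" if i < 2 else ("UNCLASSIFIED" if i == 2 else "MPA")
    for i in range(10):
        reference[f"n{i}"] = "GPA"
        old[f"n{i}"] = "MPA" if i < 2 else "GPA"
        new[f"n{i}"] = "MPA" if i == 2 else "GPA"
    result = compute_nri(reference, old, new, "MPA")
    assert (result.n1, result.n2, result.n3, result.n4) == (2, 1, 1, 2)
    assert result.nri == pytest.approx(0.2)
    assert result.nri == pytest.approx(_nri_oracle(reference, old, new, "MPA"))


def test_nri_no_reclassification_is_zero():
    reference = {"a": "MPA", "b": "GPA"}
    old = {"a": "GPA", "b": "MPA"}
    result = compute_nri(reference, old, old, "MPA")
    assert result.nri == 0.0 and result.p_value == 1.0


def test_nri_undefined_for_one_sided_reference():
    reference = {"a": "MPA", "b": "MPA"}
    other = {"a": "MPA", "b": "GPA"}
    with pytest.raises(UndefinedNRIError):
        compute_nri(reference, other, other, "MPA")


def test_nri_matches_enumeration_oracle_exhaustively():
    """All 3-vector binary label assignments over 3 patients."""
    ids = ["p0", "p1", "p2"]
    labels = ("MPA", "GPA")
    for combo in itertools.product(labels, repeat=3 * len(ids)):
        reference = dict(zip(ids, combo[0:3]))
        old = dict(zip(ids, combo[3:6]))
        new = dict(zip(ids, combo[6:9]))
        if len(set(reference.values())) < 2:
            continue
        result = compute_nri(reference, old, new, "MPA")
        assert result.nri == pytest.approx(
            _nri_oracle(reference, old, new, "MPA"), abs=1e-12
        )


@given(
    n_target=st.integers(1, 8), n_non=st.integers(1, 8),
    data=st.data(),
)
def test_nri_antisymmetry_and_bounds(n_target, n_non, data):
    ids = [f"p{i}" for i in range(n_target + n_non)]
    reference = {p: ("MPA" if i < n_target else "GPA") for i, p in enumerate(ids)}
    pick = st.sampled_from(["MPA", "GPA", "UNCLASSIFIED"])
    old = {p: data.draw(pick) for p in ids}
    new = {p: data.draw(pick) for p in ids}
    forward = compute_nri(reference, old, new, "MPA")
    backward = compute_nri(reference, new, old, "MPA")
    assert forward.nri == pytest.approx(-backward.nri)
    assert -2.0 <= forward.nri <= 2.0
    assert forward.n1 + forward.n2 <= forward.N1
    assert forward.n3 + forward.n4 <= forward.N2


@given(
    a=st.integers(0, 50), b=st.integers(0, 50),
    c=st.integers(0, 50), d=st.integers(0, 50),
    k=st.integers(1, 5),
)
def test_kappa_symmetry_scale_invariance_and_bounds(a, b, c, d, k):
    if a + b + c + d == 0:
        return
    table = AgreementTable(target_label="x", a=a, b=b, c=c, d=d)
    swapped = AgreementTable(target_label="x", a=a, b=c, c=b, d=d)
    scaled = AgreementTable(target_label="x", a=k * a, b=k * b, c=k * c, d=k * d)
    result = cohen_kappa(table)
    assert result.kappa == pytest.approx(cohen_kappa(swapped).kappa, abs=1e-12)
    assert result.kappa == pytest.approx(cohen_kappa(scaled).kappa, abs=1e-12)
    assert -1.0 <= result.kappa <= 1.0
    assert result.ci_lower <= result.kappa <= result.ci_upper
    assert 0 < result.p_value <= 1
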