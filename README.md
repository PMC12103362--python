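# aav-classify

Rule engines and agreement statistics for classifying ANCA-associated
vasculitis (AAV) into its subtypes — microscopic polyangiitis (MPA),
granulomatosis with polyangiitis (GPA) and eosinophilic granulomatosis
with polyangiitis (EGPA) — from a per-patient feature table.

It is written for clinical researchers comparing classification
instruments on retrospective cohorts. Three systems are implemented over
one patient model:

* the **EMA algorithm**: a stepwise procedure assigning exactly one label
  in the fixed order EGPA → GPA → MPA → PAN → unclassifiable, using the
  1990 ACR criteria, Lanham criteria, Chapel Hill histology definitions
  and surrogate markers;
* the **2022 ACR/EULAR criteria**: weighted additive scores with
  thresholds (GPA ≥ 5, MPA ≥ 5, EGPA ≥ 6) and no prescribed sequence, so
  a patient may satisfy several scores at once;
* the **EMA-ACR/EULAR hybrid**: the EMA step order with the 2022 scores
  substituted for the 1990 ACR instruments, restoring the single-label
  guarantee.

To compare systems the package computes 2×2 cross-classifications per
target subtype, Cohen's kappa

    κ = (p_o − p_e) / (1 − p_e)

with Fleiss–Cohen–Everitt confidence intervals, percent agreement, and
the categorical Net Reclassification Index

    NRI = (n₁ − n₂)/N₁ − (n₃ − n₄)/N₂

where a reference system splits the cohort into target (N₁) and
non-target (N₂) patients and n₁…n₄ count label movements of a new system
relative to an old one. A seedable synthetic cohort generator emulating a
pediatric, MPO-dominant AAV population makes everything testable without
access to patient data. See `docs/methods.md` for the full model
description and design choices.

## Worked example

```python
from aav_classify import (
    AncaSerology, PatientRecord, SubtypeLabel,
    classify_acr_eular_2022, classify_hybrid,
    cohen_kappa, table_from_marginals,
)

# A patient positive for both MPO- and PR3-ANCA with pauci-immune
# glomerulonephritis on renal biopsy:
patient = PatientRecord(
    patient_id="example",
    vasculitis_diagnosis_established=True,
    serology=AncaSerology(elisa_mpo="positive", elisa_pr3="positive"),
    pauci_immune_gn="present",
)
print(sorted(l.value for l in classify_acr_eular_2022(patient).labels))
print(classify_hybrid(patient).single_label().value)

# Agreement between two systems from published marginals: of 179
# patients, one system found 136 MPA and the other 145, with 121 common.
kappa = cohen_kappa(table_from_marginals("MPA", 179, 136, 145, 121))
print(round(kappa.kappa, 3), [round(v, 3) for v in kappa.ci_display()])
```

prints

```
['GPA', 'MPA']
GPA
0.357 [0.196, 0.518]
```

The first two lines show the duplicate-classification problem and its
resolution: the 2022 scores label this patient both MPA (6 + 3 − 1 = 8)
and GPA (5 + 1 − 1 = 5), while the hybrid's GPA step fires before its MPA
step and emits a single label. The last line is the chance-corrected
MPA agreement (κ = 0.357, 95% CI 0.196–0.518) between the stepwise and
weighted systems — "moderate" at best, which is why the hybrid exists.

The same is available from a shell:

```
aav-classify simulate --n 500 --seed 42 --output cohort.csv
aav-classify classify --input cohort.csv --system hybrid --summary summary.json
aav-classify compare --input cohort.csv --systems ema --systems acr2022 \
    --systems hybrid --reference ema --output report.json
```

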