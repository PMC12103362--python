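# Methods

## Problem and scope

ANCA-associated vasculitis (AAV) is a necrotizing small-vessel vasculitis
comprising three subtypes — microscopic polyangiitis (MPA), granulomatosis
with polyangiitis (GPA) and eosinophilic granulomatosis with polyangiitis
(EGPA) — whose management differs enough that subtype assignment matters.
Several classification instruments coexist, and they disagree. This package
implements three of them over a common patient-feature model, plus the
statistics needed to quantify their disagreement:

1. **EMA algorithm** — a stepwise consensus procedure that forces a single
   label per patient in a fixed order (EGPA → GPA → MPA → PAN →
   unclassifiable), built from the 1990 ACR criteria, the Lanham EGPA
   criteria, Chapel Hill (CHCC) histology definitions, and surrogate
   markers that stand in for histology.
2. **2022 ACR/EULAR criteria** — three independent weighted additive
   scores (GPA ≥ 5, MPA ≥ 5, EGPA ≥ 6). They specify no sequence, so a
   patient can meet several scores at once (duplicate classification) or
   none.
3. **EMA-ACR/EULAR hybrid** — the EMA step order with the 1990 ACR
   instruments replaced by the 2022 scores, which restores the single-label
   guarantee while using the modern, serology-aware items.

Out of scope by design: survival analysis, disease-activity scoring,
pediatric-specific (EULAR/PRES/PRINTO) criteria, eGFR computation, and any
clinical decision support. The instruments here are classification — not
diagnostic — tools; the 2022 scorers refuse to run unless
`vasculitis_diagnosis_established` is set.

## Patient model and three-valued logic

All classifiers consume a flat `PatientRecord`: binary clinical/imaging
flags (duration qualifiers such as ">1 month" pre-resolved by the
abstractor), eosinophil count (×10⁹/L) and eosinophil percentage, an organ
count for the Lanham criterion, three-valued histology
(present / absent / no_biopsy) and four three-valued ANCA assays (IIF c-
and p-ANCA patterns; ELISA PR3 and MPO).

Two conventions do most of the work for retrospective tables:

* **Unknown is neither positive nor negative.** A `no_biopsy` histology
  field contributes 0 points to every score and makes histology-gated EMA
  routes *unavailable* rather than failed; an unmeasured eosinophil count
  likewise contributes 0. Scores therefore never propagate "unknown"
  totals, matching how registry cohorts with incomplete work-ups are
  scored in practice.
* **Compound ANCA predicates.** The rules consume `PR3-ANCA (or c-ANCA)`
  and `MPO-ANCA (or p-ANCA)`. Under the default `elisa_first` policy a
  known antigen-specific ELISA result is authoritative and the IIF pattern
  is consulted only when the ELISA is unknown; `either_positive` is
  available as an alternative. No published account states how discordant
  ELISA/IIF pairs were resolved in the motivating cohort; `elisa_first`
  reflects the primacy of antigen-specific assays and is an explicit,
  configurable choice. Both policies are monotone: resolving an unknown
  assay to positive never un-fires a positive predicate.

## Rule content and configuration

Weights, thresholds and cardinality rules live in two bundled JSON configs
(`acr_eular_2022.json`, `legacy_criteria.json`) rather than in code, so a
user can swap alternative weightings via `--criteria-config`. The 2022
instruments are restricted to the items reachable from the patient model
(the vocabulary the comparison actually exercises); the 1990 ACR GPA rule
is 2-of-4, ACR EGPA 4-of-6, Lanham a 3-way conjunction, the GPA surrogate
list any-of-8, and the renal surrogate either hematuria with red-cell
casts/dysmorphic erythrocytes or 2+ hematuria with 2+ proteinuria.

Step 3 of the hybrid (MPA) is genuinely underdetermined: replacing "the
1990 ACR criteria" touches steps 1–2 only, yet published hybrid MPA totals
are not reconstructible from printed marginals under either the pure EMA
routes or the pure 2022 score. The `step3_policy` parameter therefore
exposes `ema_routes_only`, `acr2022_score_only` and `either` (default
`either`); analyses should report which policy they used. The PAN step is
retained for fidelity to the EMA framework, but emitting PAN triggers a
warning since PAN is outside AAV.

## Agreement statistics

For a target subtype, two systems' outputs are reduced to a 2×2 table
(a = both assign the target, b/c = one system only, d = neither). A
multi-label patient under the 2022 scores counts as the target only when
its label set is exactly the target (`target_only_if_pure`, default) —
the convention under which published marginals for the motivating cohort
are internally consistent; `target_if_member` is available.

* **Cohen's kappa** κ = (p_o − p_e)/(1 − p_e). The 95% CI uses the
  large-sample Fleiss–Cohen–Everitt variance (the same arrangement
  statsmodels uses, against which the implementation is cross-checked to
  1e-12); the p-value tests κ = 0 with the null-hypothesis variance and a
  two-sided z-test. CIs are truncated to [−1, 1]; the reporting layer
  additionally floors the lower bound at 0 (`ci_display`), matching the
  convention in the clinical literature this package accompanies. A
  degenerate table (p_e = 1) reports κ = 1 with a note.
* **Categorical NRI** = (n1 − n2)/N1 − (n3 − n4)/N2, where the reference
  system defines the target (N1) / non-target (N2) partition and n1…n4
  count movements of the "new" system relative to the "old" one. SE is
  √((n1+n2)/N1² + (n3+n4)/N2²) with a two-sided z-test; the estimate is
  undefined (an error, not NaN) when the reference partition is
  one-sided. The implementation is verified against an exhaustive
  enumeration oracle over all label assignments for cohorts of ≤ 5.
* **Percent agreement** a/(a+b) or a/(a+c), reported to one decimal, as
  the simple "X of Y confirmed" figures.

Rounding follows the accompanying literature: estimates to 3 decimals,
percentages to 1.

## Synthetic cohort generator

No patient-level data from the motivating multicentre pediatric cohort are
publicly available, so testing uses a seedable generator
(`cohort_default.yaml`). Four archetypes (MPA-like 76%, GPA-like 8%,
EGPA-like 2%, sparse-feature "noise" 14%) mirror that cohort's subtype
distribution; each archetype carries per-flag Bernoulli prevalences
anchored, where available, to the cohort's published subtype-conditional
frequencies (ENT involvement, hematuria, serology positivity and
missingness, …). Eosinophil counts and percentages are log-normal with
medians/sigmas chosen for their threshold exceedance probabilities
(MPA-like P(count ≥ 1×10⁹/L) ≈ 2%, EGPA-like ≈ 94%). The noise archetype
includes a 12% rate of PAN-typical angiography so every terminal of the
stepwise algorithms occurs in a default 500-patient cohort.

Deliberate simplifications — and hence what passing tests do *not* show
about real data:

* Features are conditionally independent given the archetype; real
  comorbidity correlations (e.g. MPO positivity with p-ANCA pattern
  within a patient) are not modeled beyond the archetype membership. With
  `elisa_first` resolution this does not affect classification, but the
  raw IIF columns should not be treated as clinically realistic.
* The published prevalences are conditional on *assigned* subtype, not on
  generative archetype; the spec treats them as archetype-conditional,
  a stated approximation.
* Single snapshot per patient; no follow-up, no outcomes.

Reproducibility is bit-level: the same spec + seed yields a byte-identical
CSV (single `numpy` Generator, fixed draw order; every probability is
drawn even when a branch discards it, so toggling one prevalence does not
shift the stream for unrelated fields).

## Problem sizes and numerical choices

Tests and the acceptance script use n = 500 for terminal-coverage and
agreement summaries and n = 2000 for prevalence recovery (3-SE binomial
tolerance per flag per archetype), sizes at which every check is stable
and the whole suite runs in seconds. Threshold comparisons are closed
bounds (eosinophils ≥ 1×10⁹/L; Lanham > 1.5×10⁹/L strictly, per the
original rule). Ties cannot occur elsewhere: all rules are integer
cardinalities or integer sums. p-values are floored at 1e-300 to keep
JSON serializable; CI truncation and the display floor are the only
post-hoc adjustments to any estimate.

## Known limitations

* The 2022 instruments include only the item subset reachable from the
  patient model (e.g. no serum biomarkers beyond ANCA); scores for
  patients whose classification hinges on the omitted items will differ
  from a full-instrument implementation.
* Kappa/NRI inference is asymptotic; at the 14-patient GPA marginal the
  normal approximation is rough (visible in the floored CI bound), and no
  exact or bootstrap alternative is wired in yet.
* The generator is calibrated to one East-Asian pediatric cohort profile
  (MPO/MPA-dominant); conclusions drawn from it will not transfer to
  PR3-dominant adult populations without re-specifying the YAML.
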