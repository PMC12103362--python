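{
  "version": "legacy.1",
  "rules": {
    "ACR1990_GPA": {
      "min_count": 2,
      "items": [
        "nasal_or_oral_inflammation",
        "abnormal_chest_radiograph",
        "active_urinary_sediment",
        "granulomatous_inflammation_on_biopsy"
      ]
    },
    "ACR1990_EGPA": {
      "min_count": 4,
      "items": [
        "asthma",
        "eosinophilia_gt_10pct",
        "mono_or_polyneuropathy",
        "non_fixed_pulmonary_infiltrates",
        "paranasal_sinus_abnormality",
        "extravascular_eosinophils_on_biopsy"
      ]
    },
    "LANHAM": {
      "min_count": 3,
      "items": [
        "asthma",
        "eosinophil_count_gt_1_5e9_per_l",
        "vasculitis_in_ge_2_extrapulmonary_organs"
      ]
    },
    "SURROGATE_GPA": {
      "min_count": 1,
      "items": [
        "fixed_pulmonary_infiltrates_gt1mo",
        "pulmonary_nodules_mass_cavitation",
        "bronchial_stenosis",
        "bloody_nasal_discharge_crusting_or_ulceration",
        "chronic_sinusitis_otitis_mastoiditis_gt3mo",
        "retro_orbital_mass",
        "subglottic_stenosis",
        "saddle_nose"
      ]
    },
    "SURROGATE_RENAL": {
      "min_count": 1,
      "items": [
        "hematuria_with_rbc_casts_or_dysmorphic",
        "hematuria_2plus_with_proteinuria_2plus"
      ]
    }
  }
}
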