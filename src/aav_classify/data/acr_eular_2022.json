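{
  "version": "2022.1",
  "anca_precedence": "elisa_first",
  "subtypes": {
    "GPA": {
      "threshold": 5,
      "items": [
        {"item_id": "bloody_nasal_discharge_ulcers_crusting", "field": "nasal_involvement", "weight": 3},
        {"item_id": "cartilaginous_involvement", "field": "cartilaginous_involvement", "weight": 2},
        {"item_id": "conductive_or_sensorineural_hearing_loss", "field": "hearing_loss", "weight": 1},
        {"item_id": "pr3_or_c_anca_positive", "field": "pr3_or_c_positive", "weight": 5},
        {"item_id": "pulmonary_nodules_mass_cavitation_imaging", "field": "pulmonary_nodules_mass_cavitation", "weight": 2},
        {"item_id": "granuloma_on_biopsy", "field": "granulomatous_inflammation", "weight": 2},
        {"item_id": "sinonasal_inflammation_or_mastoiditis_imaging", "field": "sinonasal_inflammation_or_mastoiditis_imaging", "weight": 1},
        {"item_id": "pauci_immune_gn_on_biopsy", "field": "pauci_immune_gn", "weight": 1},
        {"item_id": "mpo_or_p_anca_positive", "field": "mpo_or_p_positive", "weight": -1},
        {"item_id": "eosinophil_count_ge_1e9_per_l", "field": "eosinophil_count_ge_1", "weight": -4}
      ]
    },
    "MPA": {
      "threshold": 5,
      "items": [
        {"item_id": "bloody_nasal_discharge_ulcers_crusting", "field": "nasal_involvement", "weight": -3},
        {"item_id": "mpo_or_p_anca_positive", "field": "mpo_or_p_positive", "weight": 6},
        {"item_id": "lung_fibrosis_or_ild_imaging", "field": "lung_fibrosis_or_ild", "weight": 3},
        {"item_id": "pauci_immune_gn_on_biopsy", "field": "pauci_immune_gn", "weight": 3},
        {"item_id": "pr3_or_c_anca_positive", "field": "pr3_or_c_positive", "weight": -1},
        {"item_id": "eosinophil_count_ge_1e9_per_l", "field": "eosinophil_count_ge_1", "weight": -4}
      ]
    },
    "EGPA": {
      "threshold": 6,
      "items": [
        {"item_id": "obstructive_airway_disease", "field": "obstructive_airway_disease", "weight": 3},
        {"item_id": "nasal_polyps", "field": "nasal_polyps", "weight": 3},
        {"item_id": "mononeuritis_multiplex", "field": "mononeuritis_multiplex", "weight": 1},
        {"item_id": "eosinophil_count_ge_1e9_per_l", "field": "eosinophil_count_ge_1", "weight": 5},
        {"item_id": "extravascular_eosinophil_predominant_inflammation", "field": "eosinophil_predominant_extravascular_inflammation", "weight": 2},
        {"item_id": "pr3_or_c_anca_positive", "field": "pr3_or_c_positive", "weight": -3},
        {"item_id": "hematuria", "field": "hematuria", "weight": -1}
      ]
    }
  }
}
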