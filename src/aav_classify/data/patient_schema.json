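{
  "format": "csv",
  "encoding": "utf-8",
  "one_row_per": "patient (single assessment snapshot)",
  "unknown_encoding": "empty string",
  "columns": [
    {"name": "patient_id", "type": "string", "required": true},
    {"name": "age_years", "type": "number", "min": 0, "unknown_allowed": true},
    {"name": "sex", "type": "enum", "values": ["male", "female", "unknown"], "default": "unknown"},
    {"name": "iif_c_anca", "type": "tristate", "values": ["positive", "negative", "unknown"], "default": "unknown"},
    {"name": "iif_p_anca", "type": "tristate", "values": ["positive", "negative", "unknown"], "default": "unknown"},
    {"name": "elisa_pr3", "type": "tristate", "values": ["positive", "negative", "unknown"], "default": "unknown"},
    {"name": "elisa_mpo", "type": "tristate", "values": ["positive", "negative", "unknown"], "default": "unknown"},
    {"name": "eosinophil_count", "type": "number", "unit": "x10^9/L", "min": 0, "unknown_allowed": true},
    {"name": "eosinophilia_pct", "type": "number", "unit": "% of leukocytes", "min": 0, "max": 100, "unknown_allowed": true},
    {"name": "nasal_involvement", "type": "boolean", "default": false, "description": "bloody discharge, ulcers, crusting, congestion, blockage, or septal defect/perforation"},
    {"name": "cartilaginous_involvement", "type": "boolean", "default": false},
    {"name": "hearing_loss", "type": "boolean", "default": false, "description": "conductive or sensorineural"},
    {"name": "obstructive_airway_disease", "type": "boolean", "default": false, "description": "including asthma"},
    {"name": "nasal_polyps", "type": "boolean", "default": false},
    {"name": "mononeuritis_multiplex", "type": "boolean", "default": false, "description": "mononeuritis multiplex or motor/sensory polyneuropathy"},
    {"name": "oral_inflammation", "type": "boolean", "default": false, "description": "oral ulcers or inflammation"},
    {"name": "hematuria", "type": "boolean", "default": false},
    {"name": "rbc_casts_or_dysmorphic", "type": "boolean", "default": false, "description": "red-cell casts or >10% dysmorphic erythrocytes"},
    {"name": "proteinuria_2plus", "type": "boolean", "default": false},
    {"name": "hematuria_2plus", "type": "boolean", "default": false},
    {"name": "non_fixed_pulmonary_infiltrates", "type": "boolean", "default": false},
    {"name": "systemic_vasculitis_organs", "type": "integer", "min": 0, "default": 0, "description": "count of extrapulmonary organ systems with vasculitic involvement"},
    {"name": "pulmonary_nodules_mass_cavitation", "type": "boolean", "default": false},
    {"name": "fixed_pulmonary_infiltrates_gt1mo", "type": "boolean", "default": false},
    {"name": "bronchial_stenosis", "type": "boolean", "default": false},
    {"name": "sinonasal_inflammation_or_mastoiditis_imaging", "type": "boolean", "default": false},
    {"name": "paranasal_sinus_abnormality", "type": "boolean", "default": false},
    {"name": "lung_fibrosis_or_ild", "type": "boolean", "default": false},
    {"name": "retro_orbital_mass", "type": "boolean", "default": false},
    {"name": "subglottic_stenosis", "type": "boolean", "default": false},
    {"name": "saddle_nose", "type": "boolean", "default": false},
    {"name": "chronic_sinusitis_otitis_mastoiditis_gt3mo", "type": "boolean", "default": false},
    {"name": "abnormal_chest_radiograph", "type": "boolean", "default": false},
    {"name": "granulomatous_inflammation", "type": "histology", "values": ["present", "absent", "no_biopsy"], "default": "no_biopsy"},
    {"name": "pauci_immune_gn", "type": "histology", "values": ["present", "absent", "no_biopsy"], "default": "no_biopsy"},
    {"name": "eosinophil_predominant_extravascular_inflammation", "type": "histology", "values": ["present", "absent", "no_biopsy"], "default": "no_biopsy"},
    {"name": "small_vessel_vasculitis_no_granuloma", "type": "histology", "values": ["present", "absent", "no_biopsy"], "default": "no_biopsy", "description": "small-vessel vasculitis without granulomas (MPA-compatible by CHCC)"},
    {"name": "medium_vessel_necrotizing_arteritis", "type": "histology", "values": ["present", "absent", "no_biopsy"], "default": "no_biopsy", "description": "medium-vessel necrotizing arteritis (PAN-compatible by CHCC)"},
    {"name": "angiography_typical_pan", "type": "boolean", "default": false},
    {"name": "vasculitis_diagnosis_established", "type": "boolean", "default": false, "description": "entry condition for the 2022 ACR/EULAR scores"}
  ]
}
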