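{
  "iss": {"albumin": 3.5, "b2m_low": 3.5, "b2m_high": 5.5},
  "anemia": {"hb_abs": 10.0, "lln": 12.0, "lln_delta": 2.0},
  "hypercalcemia": {"ca_abs": 2.75, "uln": 2.55, "uln_delta": 0.25},
  "renal": {"creatinine": 2.0, "egfr": 40.0},
  "bone": {"min_lesions": 1},
  "slim": {"plasma_cell_pct": 60.0, "flc_ratio": 100.0, "mri_focal_lesions": 1},
  "fitness": {"age_bands": [65, 75], "ecog_bands": [1, 2], "cci_bands": [1, 3], "class_bands": [1, 3]}
}
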