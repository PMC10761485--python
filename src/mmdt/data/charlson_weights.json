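{
  "myocardial_infarction": 1,
  "congestive_heart_failure": 1,
  "peripheral_vascular_disease": 1,
  "cerebrovascular_disease": 1,
  "dementia": 1,
  "chronic_pulmonary_disease": 1,
  "rheumatic_disease": 1,
  "peptic_ulcer_disease": 1,
  "mild_liver_disease": 1,
  "diabetes_without_complication": 1,
  "diabetes_with_complication": 2,
  "hemiplegia": 2,
  "renal_disease": 2,
  "malignancy": 2,
  "moderate_severe_liver_disease": 3,
  "metastatic_solid_tumor": 6,
  "aids": 6
}
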