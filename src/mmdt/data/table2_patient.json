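{
  "schema_version": 1,
  "patient_id": "example-mm-patient",
  "therapy_line": 1,
  "decision_date": "2023-06-01",
  "refractory_substances": [],
  "observations": [
    {"entity": "age", "value": 55, "unit": "years", "date": "2023-05-20"},
    {"entity": "ecog", "value": 0, "unit": "", "date": "2023-05-20"},
    {"entity": "cci", "value": 2, "unit": "", "date": "2023-05-20"},
    {"entity": "t_4_14", "value": "no", "date": "2023-05-12"},
    {"entity": "t_14_16", "value": "no", "date": "2023-05-12"},
    {"entity": "del_17p", "value": "no", "date": "2023-05-12"},
    {"entity": "gain_1q21", "value": "no", "date": "2023-05-12"},
    {"entity": "t_14_20", "value": "no", "date": "2023-05-12"},
    {"code": {"system": "LOINC", "code": "1751-7"}, "value": 3.1, "unit": "g/dl", "date": "2023-05-18"},
    {"entity": "b2m", "value": 3.3, "unit": "mg/L", "date": "2023-05-18"}
  ]
}
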