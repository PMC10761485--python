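{
  "schema_version": 1,
  "regimens": [
    {
      "id": "VRD_ASCT",
      "display": "Bortezomib, Lenalidomide, Dexamethasone + ASCT",
      "substances": ["bortezomib", "lenalidomide", "dexamethasone"],
      "includes_asct": true,
      "maintenance_options": ["bortezomib", "lenalidomide", "ixazomib"],
      "cpg_status": "cpg_compliant",
      "therapy_line": 1,
      "eligibility_rules": [{"measure": "fitness", "in": ["fit"]}],
      "warning_rules": [
        {"entity": "creatinine", "op": "gt", "value": 1.2,
         "message": "creatinine above reference range: dose reduction recommended for lenalidomide"}
      ]
    },
    {
      "id": "VCD_ASCT",
      "display": "Bortezomib, Cyclophosphamide, Dexamethasone + ASCT",
      "substances": ["bortezomib", "cyclophosphamide", "dexamethasone"],
      "includes_asct": true,
      "maintenance_options": ["bortezomib", "lenalidomide", "ixazomib"],
      "cpg_status": "cpg_compliant",
      "therapy_line": 1,
      "eligibility_rules": [{"measure": "fitness", "in": ["fit"]}],
      "warning_rules": [
        {"entity": "creatinine", "op": "gt", "value": 1.2,
         "message": "creatinine above reference range: hydration and dose review recommended for cyclophosphamide"}
      ]
    },
    {
      "id": "VRD",
      "display": "Bortezomib, Lenalidomide, Dexamethasone",
      "substances": ["bortezomib", "lenalidomide", "dexamethasone"],
      "includes_asct": false,
      "maintenance_options": [],
      "cpg_status": "cpg_compliant",
      "therapy_line": 1,
      "eligibility_rules": [{"measure": "fitness", "in": ["intermediate", "frail"]}],
      "warning_rules": [
        {"entity": "creatinine", "op": "gt", "value": 1.2,
         "message": "creatinine above reference range: dose reduction recommended for lenalidomide"}
      ]
    },
    {
      "id": "VCD",
      "display": "Bortezomib, Cyclophosphamide, Dexamethasone",
      "substances": ["bortezomib", "cyclophosphamide", "dexamethasone"],
      "includes_asct": false,
      "maintenance_options": [],
      "cpg_status": "cpg_compliant",
      "therapy_line": 1,
      "eligibility_rules": [{"measure": "fitness", "in": ["intermediate", "frail"]}],
      "warning_rules": []
    }
  ]
}
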