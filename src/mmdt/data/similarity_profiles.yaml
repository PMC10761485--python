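# Endpoint-specific twin-cohort similarity profiles.
#
# Per endpoint: which derived similarity measures a retrospective case must
# match exactly (cases with the measure unknown are excluded).  Context
# constraints (same regimen, same therapy line, same treatment stage) always
# apply.  Defaults mirror the reference configuration: remission, time to next
# treatment and early mortality constrain all three measures; quality of life
# and adverse events constrain fitness only.
schema_version: 1
min_cohort_size: 10
profiles:
  remission:
    constrained: [fitness, high_risk_cytogenetics, iss_stage]
  ttnt:
    constrained: [fitness, high_risk_cytogenetics, iss_stage]
  em:
    constrained: [fitness, high_risk_cytogenetics, iss_stage]
  qol:
    constrained: [fitness]
  ae:
    constrained: [fitness]
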