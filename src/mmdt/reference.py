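"""Reference myeloma knowledge base and operator registry.

A reduced but self-consistent instance of the entity network: every entity
the worked example, the operator pack, the five endpoints, the regimen
registry and the warning rules touch, with representative LOINC/SNOMED-CT
bindings.  Built programmatically so the TURTLE export, the registries and
the tests always agree.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import scores
from .engine import MANDATORY, OperatorRegistry, OperatorSpec
from .knowledge import CALCULATED, OBSERVED, CodeBinding, EntityDescriptor, EntityNetwork, ValueDomain
from .tristate import TriState, UNKNOWN
from .values import ClinicalValue

SIMILARITY_TARGETS = ("fitness", "high_risk_cytogenetics", "iss_stage")

SUBSTANCES = ("bortezomib", "lenalidomide", "cyclophosphamide", "dexamethasone", "ixazomib")

ENDPOINT_OUTCOME_ENTITIES = (
    "remission_post_induction", "remission_post_asct", "ttnt_days",
    "ae_grade3plus", "qlq_c30_global", "qlq_my20_disease_symptoms",
    "qlq_my20_side_effects", "early_mortality",
)


def _num(id_, label, unit, rng=None, codes=(), fhir="Observation"):
    return EntityDescriptor(id_, label, OBSERVED,
                            ValueDomain("numeric", unit=unit, range=rng),
                            tuple(codes), fhir)


def _bool(id_, label, codes=(), fhir="Observation"):
    return EntityDescriptor(id_, label, OBSERVED, ValueDomain("boolean"), tuple(codes), fhir)


def _calc(id_, label, domain):
    return EntityDescriptor(id_, label, CALCULATED, domain, (), "Observation")


def build_reference_network() -> EntityNetwork:
    n = EntityNetwork()

    # demographics / performance / comorbidity
    n.add_entity(_num("age", "Age", "years", (0, 120),
                      [CodeBinding("LOINC", "30525-0", "Age")]))
    n.add_entity(_num("ecog", "ECOG performance status", "dimensionless", (0, 5),
                      [CodeBinding("LOINC", "89247-1", "ECOG Performance Status score")]))
    n.add_entity(_num("karnofsky", "Karnofsky performance status", "dimensionless", (0, 100),
                      [CodeBinding("LOINC", "89243-0", "Karnofsky Performance Status score")]))
    for condition in sorted(scores.CHARLSON_WEIGHTS):
        n.add_entity(_bool(f"charlson_{condition}", f"Charlson condition: {condition.replace('_', ' ')}",
                           fhir="Condition"))

    # laboratory
    n.add_entity(_num("hemoglobin", "Hemoglobin", "g/dl", (0, 25),
                      [CodeBinding("LOINC", "718-7", "Hemoglobin [Mass/volume] in Blood")]))
    n.add_entity(_num("calcium", "Total serum calcium", "mmol/l", (0, 6),
                      [CodeBinding("LOINC", "17861-6", "Calcium [Mass/volume] in Serum or Plasma")]))
    n.add_entity(_num("creatinine", "Serum creatinine", "mg/dl", (0, 30),
                      [CodeBinding("LOINC", "2160-0", "Creatinine [Mass/volume] in Serum or Plasma")]))
    n.add_entity(_num("egfr", "Estimated glomerular filtration rate", "ml/min", (0, 250),
                      [CodeBinding("LOINC", "62238-1", "GFR/1.73 sq M estimated")]))
    n.add_entity(_num("albumin", "Serum albumin", "g/dl", (0, 10),
                      [CodeBinding("LOINC", "1751-7", "Albumin [Mass/volume] in Serum or Plasma")]))
    n.add_entity(_num("b2m", "Beta-2-microglobulin", "mg/l", (0, 100),
                      [CodeBinding("LOINC", "1952-1", "Beta-2-Microglobulin [Mass/volume] in Serum")]))

    # cytogenetics and biomarkers
    marker_labels = {"t_4_14": "t(4;14)", "t_14_16": "t(14;16)", "del_17p": "del(17p)",
                     "gain_1q21": "gain(1q21)", "t_14_20": "t(14;20)"}
    for marker, label in marker_labels.items():
        n.add_entity(_bool(marker, f"Cytogenetic aberration {label}",
                           [CodeBinding("internal", f"cyto-{marker}", label)]))
    n.add_entity(_num("bone_lesion_count", "Osteolytic bone lesion count", "dimensionless", (0, 500)))
    n.add_entity(_num("plasma_cell_pct", "Clonal bone-marrow plasma cells", "%", (0, 100)))
    n.add_entity(_num("flc_ratio", "Involved/uninvolved free light chain ratio", "dimensionless", (0, 10000)))
    n.add_entity(_num("mri_focal_lesions", "Focal lesions on MRI", "dimensionless", (0, 500)))

    # treatment context
    n.add_entity(EntityDescriptor("multiple_myeloma", "Multiple myeloma", OBSERVED,
                                  ValueDomain("boolean"),
                                  (CodeBinding("SNOMED-CT", "109989006", "Multiple myeloma"),),
                                  "Condition"))
    n.add_entity(_num("therapy_line", "Therapy line", "dimensionless", (1, 20), fhir="CarePlan"))
    n.add_entity(EntityDescriptor("asct", "Autologous stem cell transplantation", OBSERVED,
                                  ValueDomain("boolean"),
                                  (CodeBinding("SNOMED-CT", "425843001", "Autologous stem cell transplant"),),
                                  "Procedure"))
    for substance in SUBSTANCES:
        n.add_entity(_bool(substance, f"Substance: {substance}", fhir="MedicationStatement"))
        n.add_entity(_bool(f"refractory_{substance}", f"Refractory to {substance}", fhir="Condition"))
    for regimen in ("vrd", "vcd", "vrd_asct", "vcd_asct",
                    "maintenance_bortezomib", "maintenance_lenalidomide", "maintenance_ixazomib"):
        n.add_entity(_bool(regimen, f"Regimen: {regimen.upper().replace('_', ' ')}", fhir="CarePlan"))

    # recorded endpoints
    remission_domain = ValueDomain("categorical", categories=scores.REMISSION_CATEGORIES)
    n.add_entity(EntityDescriptor("remission_post_induction", "Remission category after induction",
                                  OBSERVED, remission_domain))
    n.add_entity(EntityDescriptor("remission_post_asct", "Remission category after ASCT",
                                  OBSERVED, remission_domain))
    n.add_entity(_num("ttnt_days", "Time to next treatment", "days", (0, 20000)))
    n.add_entity(_bool("ae_grade3plus", "Adverse event grade >= 3"))
    n.add_entity(_num("qlq_c30_global", "EORTC QLQ-C30 global health score", "dimensionless", (0, 100)))
    n.add_entity(_num("qlq_my20_disease_symptoms", "EORTC QLQ-MY20 disease symptoms scale", "dimensionless", (0, 100)))
    n.add_entity(_num("qlq_my20_side_effects", "EORTC QLQ-MY20 side effects scale", "dimensionless", (0, 100)))
    n.add_entity(_bool("early_mortality", "Death within 100 days after ASCT"))

    # calculated entities
    tri = ValueDomain("boolean")
    n.add_entity(_calc("anemia", "Anemia", tri))
    n.add_entity(_calc("hypercalcemia", "Hypercalcemia", tri))
    n.add_entity(_calc("renal_insufficiency", "Renal insufficiency", tri))
    n.add_entity(_calc("bone_lesions_present", "Osteolytic bone lesions present", tri))
    n.add_entity(_calc("crab", "CRAB end-organ damage criteria", tri))
    n.add_entity(_calc("slim", "SLiM biomarker criteria", tri))
    n.add_entity(_calc("iss_stage", "ISS stage", ValueDomain("categorical", categories=("1", "2", "3"))))
    n.add_entity(_calc("cci", "Charlson comorbidity index", ValueDomain("numeric", unit="dimensionless", range=(0, 37))))
    n.add_entity(_calc("ecog_proxy", "ECOG derived from Karnofsky", ValueDomain("numeric", unit="dimensionless", range=(0, 5))))
    n.add_entity(_calc("fitness", "Overall fitness", ValueDomain("categorical", categories=scores.FITNESS_CLASSES)))
    n.add_entity(_calc("high_risk_cytogenetics", "High-risk cytogenetics", tri))

    # derives edges (operator inputs -> outputs)
    for src, dst in _derives_pairs():
        n.add_edge(src, dst, "derives")

    # regimen composition and indication
    for regimen, subs in (("vrd", ("bortezomib", "lenalidomide", "dexamethasone")),
                          ("vcd", ("bortezomib", "cyclophosphamide", "dexamethasone"))):
        for s in subs:
            n.add_edge(regimen, s, "contains")
            n.add_edge(f"{regimen}_asct", s, "contains")
        n.add_edge(f"{regimen}_asct", "asct", "contains")
    for maint, sub in (("maintenance_bortezomib", "bortezomib"),
                       ("maintenance_lenalidomide", "lenalidomide"),
                       ("maintenance_ixazomib", "ixazomib")):
        n.add_edge(maint, sub, "contains")
    for regimen in ("vrd", "vcd", "vrd_asct", "vcd_asct",
                    "maintenance_bortezomib", "maintenance_lenalidomide", "maintenance_ixazomib"):
        n.add_edge(regimen, "multiple_myeloma", "treats")

    # which similarity measures influence which recorded endpoints
    for endpoint_entity in ENDPOINT_OUTCOME_ENTITIES:
        n.add_edge("fitness", endpoint_entity, "influences")
    for endpoint_entity in ("remission_post_induction", "remission_post_asct", "ttnt_days", "early_mortality"):
        n.add_edge("high_risk_cytogenetics", endpoint_entity, "influences")
        n.add_edge("iss_stage", endpoint_entity, "influences")
    return n


def _derives_pairs() -> list[tuple[str, str]]:
    pairs = [("hemoglobin", "anemia"), ("calcium", "hypercalcemia"),
             ("creatinine", "renal_insufficiency"), ("egfr", "renal_insufficiency"),
             ("bone_lesion_count", "bone_lesions_present"),
             ("anemia", "crab"), ("renal_insufficiency", "crab"),
             ("hypercalcemia", "crab"), ("bone_lesions_present", "crab"),
             ("plasma_cell_pct", "slim"), ("flc_ratio", "slim"), ("mri_focal_lesions", "slim"),
             ("albumin", "iss_stage"), ("b2m", "iss_stage"),
             ("karnofsky", "ecog_proxy"),
             ("age", "fitness"), ("ecog", "fitness"), ("karnofsky", "fitness"), ("cci", "fitness")]
    pairs += [(f"charlson_{c}", "cci") for c in sorted(scores.CHARLSON_WEIGHTS)]
    pairs += [(m, "high_risk_cytogenetics") for m in scores.CYTOGENETIC_MARKERS]
    return pairs


# ---------------------------------------------------------------------------
# Operator rules over ClinicalValue inputs
# ---------------------------------------------------------------------------

def _tri(value: TriState) -> ClinicalValue:
    return ClinicalValue.tristate(value)


def _rule_anemia(inputs):
    return _tri(scores.anemia(inputs["hemoglobin"].as_number()))


def _rule_hypercalcemia(inputs):
    return _tri(scores.hypercalcemia(inputs["calcium"].as_number()))


def _rule_renal(inputs):
    return _tri(scores.renal_insufficiency(inputs["creatinine"].as_number(),
                                           inputs["egfr"].as_number()))


def _rule_bone(inputs):
    return _tri(scores.bone_lesions(inputs["bone_lesion_count"].as_number()))


def _rule_crab(inputs):
    return _tri(scores.crab(inputs["anemia"].as_tristate(),
                            inputs["renal_insufficiency"].as_tristate(),
                            inputs["hypercalcemia"].as_tristate(),
                            inputs["bone_lesions_present"].as_tristate()))


def _rule_slim(inputs):
    return _tri(scores.slim(inputs["plasma_cell_pct"].as_number(),
                            inputs["flc_ratio"].as_number(),
                            inputs["mri_focal_lesions"].as_number()))


def _rule_iss(inputs):
    stage = scores.iss_stage(inputs["albumin"].as_number(), inputs["b2m"].as_number())
    return ClinicalValue.unknown() if stage is None else ClinicalValue.category(str(stage))


def _rule_cci(inputs):
    states = {c: inputs[f"charlson_{c}"].as_tristate() for c in scores.CHARLSON_WEIGHTS}
    if all(s is UNKNOWN for s in states.values()):
        return ClinicalValue.unknown()
    total = sum(scores.CHARLSON_WEIGHTS[c] for c, s in states.items() if s is TriState.YES)
    return ClinicalValue.number(total, "dimensionless")


def _rule_ecog_proxy(inputs):
    grade = scores.ecog_from_karnofsky(inputs["karnofsky"].as_number())
    return ClinicalValue.unknown() if grade is None else ClinicalValue.number(grade, "dimensionless")


def _rule_fitness(inputs):
    ecog = inputs["ecog"].as_number()
    cci = inputs["cci"].as_number()
    cls = scores.fitness(age=inputs["age"].as_number(),
                         ecog=None if ecog is None else int(ecog),
                         kps=inputs["karnofsky"].as_number(),
                         cci=None if cci is None else int(cci))
    return ClinicalValue.unknown() if cls is None else ClinicalValue.category(cls)


def _rule_hrc(inputs):
    return _tri(scores.high_risk_cytogenetics(*(inputs[m].as_tristate()
                                                for m in scores.CYTOGENETIC_MARKERS)))


def build_reference_registry() -> OperatorRegistry:
    registry = OperatorRegistry()
    registry.register(OperatorSpec("op_anemia", "anemia", ("hemoglobin",), _rule_anemia))
    registry.register(OperatorSpec("op_hypercalcemia", "hypercalcemia", ("calcium",), _rule_hypercalcemia))
    registry.register(OperatorSpec("op_renal_insufficiency", "renal_insufficiency",
                                   ("creatinine", "egfr"), _rule_renal))
    registry.register(OperatorSpec("op_bone_lesions", "bone_lesions_present",
                                   ("bone_lesion_count",), _rule_bone))
    registry.register(OperatorSpec("op_crab", "crab",
                                   ("anemia", "renal_insufficiency", "hypercalcemia", "bone_lesions_present"),
                                   _rule_crab))
    registry.register(OperatorSpec("op_slim", "slim",
                                   ("plasma_cell_pct", "flc_ratio", "mri_focal_lesions"), _rule_slim))
    registry.register(OperatorSpec("op_iss", "iss_stage", ("albumin", "b2m"), _rule_iss))
    registry.register(OperatorSpec("op_cci", "cci",
                                   tuple(f"charlson_{c}" for c in sorted(scores.CHARLSON_WEIGHTS)),
                                   _rule_cci))
    registry.register(OperatorSpec("op_ecog_from_karnofsky", "ecog_proxy", ("karnofsky",), _rule_ecog_proxy))
    registry.register(OperatorSpec("op_fitness", "fitness",
                                   ("age", "ecog", "karnofsky", "cci"), _rule_fitness,
                                   requiredness={"age": MANDATORY}))
    registry.register(OperatorSpec("op_high_risk_cytogenetics", "high_risk_cytogenetics",
                                   scores.CYTOGENETIC_MARKERS, _rule_hrc))
    registry.check_acyclic()
    return registry


@dataclass(frozen=True)
class ReferenceKB:
    network: EntityNetwork
    registry: OperatorRegistry


def load_reference_kb() -> ReferenceKB:
    return ReferenceKB(network=build_reference_network(), registry=build_reference_registry())
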