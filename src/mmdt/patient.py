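"""In-memory patient profile: normalized observations plus therapy context."""

from __future__ import annotations

from dataclasses import dataclass, field

from .values import ClinicalValue


@dataclass
class PatientProfile:
    """A patient's raw observations resolved against the knowledge base.

    ``observations`` maps entity id to the unit-normalized latest value at or
    before the decision date.  ``raw_observations`` keeps the original records
    for provenance.
    """

    patient_id: str
    therapy_line: int = 1
    decision_date: str | None = None
    refractory_substances: tuple[str, ...] = ()
    observations: dict[str, ClinicalValue] = field(default_factory=dict)
    raw_observations: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_fhir_json(self) -> dict:
        """FHIR-shaped export: a Bundle of Observation-like resources.

        A documented field mapping, not full profile conformance.
        """
        entries = []
        for rec in self.raw_observations:
            resource: dict = {"resourceType": "Observation", "status": "final"}
            code: dict = {}
            if "code" in rec:
                code["coding"] = [dict(rec["code"])]
            if "entity" in rec:
                code.setdefault("coding", []).append(
                    {"system": "internal", "code": rec["entity"]})
            resource["code"] = code
            value = rec.get("value")
            if isinstance(value, (int, float)):
                resource["valueQuantity"] = {"value": value, "unit": rec.get("unit", "")}
            else:
                resource["valueString"] = str(value)
            if rec.get("date"):
                resource["effectiveDateTime"] = rec["date"]
            entries.append({"resource": resource})
        return {"resourceType": "Bundle", "type": "collection",
                "id": self.patient_id, "entry": entries}
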