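"""Reading and writing the canonical JSON artifacts.

Patient profiles are FHIR-Observation-shaped JSON records (coded entity,
value, unit, date); values are validated against the knowledge base's value
domains and normalized to each entity's canonical unit on load.  Repeated
measurements reduce to the latest value at or before the decision date.
Assessment reports round-trip losslessly with stable key ordering.
"""

from __future__ import annotations

import json
from datetime import date as _date

from .knowledge import EntityNetwork
from .outcomes import AssessmentReport
from .patient import PatientProfile
from .tristate import TriState
from .values import ClinicalValue, UnitError, normalize_unit

PATIENT_SCHEMA_VERSION = 1


class SchemaError(ValueError):
    def __init__(self, path: str, message: str):
        super().__init__(f"{path}: {message}")
        self.field_path = path


def _code_index(network: EntityNetwork) -> dict[tuple[str, str], str]:
    index = {}
    for eid, desc in network.entities.items():
        for cb in desc.code_bindings:
            index[(cb.system, cb.code)] = eid
    return index


def _parse_date(raw: str | None, path: str) -> _date | None:
    if raw is None:
        return None
    try:
        return _date.fromisoformat(str(raw))
    except ValueError as exc:
        raise SchemaError(path, f"unparseable ISO-8601 date {raw!r}") from exc


_TRUTHY = {"yes", "true", "1", "present"}
_FALSY = {"no", "false", "0", "absent"}


def _parse_value(entity_id: str, domain, value, unit: str, path: str) -> ClinicalValue:
    if domain.kind == "numeric":
        try:
            magnitude = float(value)
        except (TypeError, ValueError) as exc:
            raise SchemaError(path, f"numeric value expected for {entity_id}, got {value!r}") from exc
        canonical = domain.unit
        try:
            normalized = normalize_unit(magnitude, unit or canonical, canonical)
        except UnitError as exc:
            raise SchemaError(path, str(exc)) from exc
        return ClinicalValue.number(normalized, canonical)
    if domain.kind == "boolean":
        if isinstance(value, bool):
            return ClinicalValue.tristate(TriState.from_bool(value))
        token = str(value).strip().lower()
        if token in _TRUTHY:
            return ClinicalValue.tristate(TriState.YES)
        if token in _FALSY:
            return ClinicalValue.tristate(TriState.NO)
        if token == "unknown":
            return ClinicalValue.unknown()
        raise SchemaError(path, f"boolean value expected for {entity_id}, got {value!r}")
    if domain.kind == "categorical":
        label = str(value)
        if label not in domain.categories:
            raise SchemaError(path, f"value {label!r} not in declared categories of {entity_id}")
        return ClinicalValue.category(label)
    return ClinicalValue.date_value(str(value))


def read_patient(path, kb) -> PatientProfile:
    """Load and validate a patient profile JSON against the knowledge base.

    Unknown entity codes are collected as warnings (the record is skipped);
    structural problems raise :class:`SchemaError` with the field path.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    network = kb.network if hasattr(kb, "network") else kb

    if not raw.get("patient_id"):
        raise SchemaError("patient_id", "mandatory field missing")
    version = raw.get("schema_version", PATIENT_SCHEMA_VERSION)
    if version != PATIENT_SCHEMA_VERSION:
        raise SchemaError("schema_version", f"unsupported version {version!r}")

    decision = _parse_date(raw.get("decision_date"), "decision_date")
    profile = PatientProfile(
        patient_id=str(raw["patient_id"]),
        therapy_line=int(raw.get("therapy_line", 1)),
        decision_date=raw.get("decision_date"),
        refractory_substances=tuple(raw.get("refractory_substances", ())),
    )

    index = _code_index(network)
    # latest-value-wins at or before the decision date; undated records are
    # usable but overridden by any dated one
    best: dict[str, tuple[int, _date | None, ClinicalValue]] = {}
    for position, rec in enumerate(raw.get("observations", [])):
        path_here = f"observations[{position}]"
        entity_id = rec.get("entity")
        if entity_id is None and "code" in rec:
            code = rec["code"]
            entity_id = index.get((code.get("system", ""), code.get("code", "")))
            if entity_id is None:
                profile.warnings.append(
                    f"{path_here}: unknown code {code.get('system')}|{code.get('code')}, record skipped")
                continue
        if entity_id is None:
            raise SchemaError(path_here, "record needs an 'entity' id or a 'code'")
        if entity_id not in network.entities:
            profile.warnings.append(f"{path_here}: unknown entity {entity_id!r}, record skipped")
            continue
        if "value" not in rec:
            raise SchemaError(path_here, "record missing 'value'")
        obs_date = _parse_date(rec.get("date"), f"{path_here}.date")
        if decision is not None and obs_date is not None and obs_date > decision:
            profile.warnings.append(
                f"{path_here}: observation of {entity_id} dated after decision date, ignored")
            continue
        value = _parse_value(entity_id, network.entities[entity_id].value_domain,
                             rec["value"], str(rec.get("unit", "")), path_here)
        key = (0 if obs_date is None else 1, obs_date or _date.min, value)
        current = best.get(entity_id)
        if current is None or (key[0], key[1]) >= (current[0], current[1]):
            best[entity_id] = key
        profile.raw_observations.append(dict(rec))
    profile.observations = {eid: v for eid, (_, _, v) in best.items()}
    return profile


def write_report(report: AssessmentReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_jsonable(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> AssessmentReport:
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    return AssessmentReport.from_jsonable(data)
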