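"""Outcome simulation: per-regimen, per-endpoint assessment from twin cohorts.

For each eligible regimen the endpoint-specific twin cohort supplies an
empirical probability distribution (categorical endpoints), a mean time to
next treatment, or a comparative quality-of-life summary.  Regimens are
labeled with their guideline status and annotated with warnings and hard
conflicts; no option is ever ranked or flagged "best" — interpretation is
left to the physician.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from statistics import mean, median

from . import scores
from .characterize import derive_similarity_features
from .engine import trace_summary
from .matching import (ENDPOINTS, InsufficientCharacterizationError,
                       RWEDatabase, SimilarityProfile, TwinCohort, match_cohort,
                       profiles_hash)
from .patient import PatientProfile
from .scores import SimilarityFeatures
from .tristate import TriState

REPORT_SCHEMA_VERSION = 1

POST_INDUCTION = "post_induction"
POST_ASCT = "post_asct"

QOL_BINS = ("worse_than_typical", "typical", "better_than_typical")


# ---------------------------------------------------------------------------
# Regimens
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WarningRule:
    entity: str
    op: str          # gt | ge | lt | le | is_yes
    value: float | None
    message: str

    def triggered(self, profile: PatientProfile) -> TriState:
        obs = profile.observations.get(self.entity)
        if obs is None or obs.is_unknown():
            return TriState.UNKNOWN
        if self.op == "is_yes":
            return obs.as_tristate()
        magnitude = obs.as_number()
        if magnitude is None:
            return TriState.UNKNOWN
        hit = {"gt": magnitude > self.value, "ge": magnitude >= self.value,
               "lt": magnitude < self.value, "le": magnitude <= self.value}[self.op]
        return TriState.from_bool(hit)


@dataclass(frozen=True)
class EligibilityRule:
    measure: str
    allowed: tuple[str, ...]

    def satisfied(self, features: SimilarityFeatures) -> bool | None:
        value = features.get(self.measure)
        if value is None:
            return None
        return str(value) in self.allowed


@dataclass(frozen=True)
class Regimen:
    id: str
    display: str
    substances: tuple[str, ...]
    includes_asct: bool
    maintenance_options: tuple[str, ...]
    cpg_status: str
    therapy_line: int
    eligibility_rules: tuple[EligibilityRule, ...] = ()
    warning_rules: tuple[WarningRule, ...] = ()

    def __post_init__(self) -> None:
        if not self.substances:
            raise ValueError(f"regimen {self.id} without substances")
        if self.cpg_status not in ("cpg_compliant", "off_label"):
            raise ValueError(f"regimen {self.id}: unknown cpg status {self.cpg_status!r}")
        if self.maintenance_options and not self.includes_asct:
            raise ValueError(f"regimen {self.id}: maintenance only follows ASCT strategies")


def load_regimens(path=None) -> dict[str, Regimen]:
    if path is None:
        with resources.files("mmdt.data").joinpath("regimens.json").open("r", encoding="utf-8") as fh:
            raw = json.load(fh)
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
    out: dict[str, Regimen] = {}
    for item in raw["regimens"]:
        regimen = Regimen(
            id=item["id"], display=item["display"],
            substances=tuple(item["substances"]),
            includes_asct=bool(item["includes_asct"]),
            maintenance_options=tuple(item.get("maintenance_options", ())),
            cpg_status=item["cpg_status"],
            therapy_line=int(item.get("therapy_line", 1)),
            eligibility_rules=tuple(EligibilityRule(r["measure"], tuple(r["in"]))
                                    for r in item.get("eligibility_rules", ())),
            warning_rules=tuple(WarningRule(r["entity"], r["op"], r.get("value"), r["message"])
                                for r in item.get("warning_rules", ())),
        )
        out[regimen.id] = regimen
    return out


def cpg_compliant_ids(regimens: dict[str, Regimen]) -> set[str]:
    return {rid for rid, r in regimens.items() if r.cpg_status == "cpg_compliant"}


@dataclass(frozen=True)
class Conflict:
    regimen_id: str
    reason: str


def candidate_options(features: SimilarityFeatures, profile: PatientProfile,
                      regimens: dict[str, Regimen]) -> tuple[list[Regimen], list[Conflict]]:
    """Regimens for the patient's line, minus refractory and ineligible ones.

    Excluded regimens are retained as conflicts with their reason; an
    eligibility rule that cannot be decided (unknown measure) is conservative
    and excludes the option.
    """
    options: list[Regimen] = []
    conflicts: list[Conflict] = []
    refractory = {s.lower() for s in profile.refractory_substances}
    for rid in sorted(regimens):
        regimen = regimens[rid]
        if regimen.therapy_line != profile.therapy_line:
            continue
        hit = sorted(refractory & set(regimen.substances))
        if hit:
            conflicts.append(Conflict(rid, f"refractory: {', '.join(hit)}"))
            continue
        excluded = False
        for rule in regimen.eligibility_rules:
            verdict = rule.satisfied(features)
            if verdict is False:
                conflicts.append(Conflict(rid, f"eligibility: {rule.measure} must be in "
                                               f"{list(rule.allowed)}, patient is {features.get(rule.measure)!r}"))
                excluded = True
                break
            if verdict is None:
                conflicts.append(Conflict(rid, f"eligibility undetermined: {rule.measure} unknown"))
                excluded = True
                break
        if not excluded:
            options.append(regimen)
    return options, conflicts


# ---------------------------------------------------------------------------
# Endpoint results
# ---------------------------------------------------------------------------

@dataclass
class EndpointResult:
    endpoint: str
    stage: str | None
    cohort_size: int
    n_contributing: int
    n_missing_outcome: int
    distribution: dict[str, float] | None = None
    headline_state: str | None = None
    mean_days: float | None = None
    summary: dict | None = None
    low_evidence: bool = False
    flags: list[str] = field(default_factory=list)

    def to_jsonable(self) -> dict:
        return {
            "endpoint": self.endpoint, "stage": self.stage,
            "cohort_size": self.cohort_size, "n_contributing": self.n_contributing,
            "n_missing_outcome": self.n_missing_outcome,
            "distribution": self.distribution, "headline_state": self.headline_state,
            "mean_days": self.mean_days, "summary": self.summary,
            "low_evidence": self.low_evidence, "flags": list(self.flags),
        }

    @classmethod
    def from_jsonable(cls, data: dict) -> "EndpointResult":
        return cls(**data)


def _categorical_result(endpoint: str, stage: str | None, cohort: TwinCohort,
                        values: list[str | None], category_order: tuple[str, ...]) -> EndpointResult:
    recorded = [v for v in values if v is not None]
    n_missing = len(values) - len(recorded)
    result = EndpointResult(endpoint=endpoint, stage=stage, cohort_size=cohort.size,
                            n_contributing=len(recorded), n_missing_outcome=n_missing,
                            low_evidence=cohort.low_evidence)
    if not recorded:
        result.flags.append("no_evidence")
        result.distribution = {}
        return result
    counts = {c: 0 for c in category_order}
    for v in recorded:
        counts[v] = counts.get(v, 0) + 1
    total = len(recorded)
    result.distribution = {c: counts[c] / total for c in counts if counts[c] > 0}
    # headline: maximum proportion; ties resolved by the declared category order
    best = max(result.distribution.values())
    for c in category_order:
        if result.distribution.get(c) == best:
            result.headline_state = c
            break
    return result


def endpoint_distribution(cohort: TwinCohort, db: RWEDatabase, endpoint: str,
                          stage: str | None = None) -> EndpointResult:
    """Empirical outcome-state distribution of a categorical endpoint.

    Cohort members without a recorded state at the stage are excluded from
    the denominator and reported in ``n_missing_outcome``.
    """
    cases = [db.case(cid) for cid in cohort.case_ids]
    if endpoint == "remission":
        column = "remission_post_asct" if stage == POST_ASCT else "remission_post_induction"
        values = [getattr(c, column) for c in cases]
        return _categorical_result(endpoint, stage or POST_INDUCTION, cohort, values,
                                   scores.REMISSION_CATEGORIES)
    if endpoint == "ae":
        values = [None if c.ae_grade3plus is None else ("yes" if c.ae_grade3plus else "no")
                  for c in cases]
        return _categorical_result(endpoint, None, cohort, values, ("no", "yes"))
    if endpoint == "em":
        values = [None if c.early_mortality is None else ("yes" if c.early_mortality else "no")
                  for c in cases]
        return _categorical_result(endpoint, None, cohort, values, ("no", "yes"))
    raise ValueError(f"endpoint {endpoint!r} is not categorical")


def ttnt_mean(cohort: TwinCohort, db: RWEDatabase) -> EndpointResult:
    """Mean days to next treatment over cohort members with a recorded start."""
    days = [db.case(cid).ttnt_days for cid in cohort.case_ids]
    recorded = [d for d in days if d is not None]
    result = EndpointResult(endpoint="ttnt", stage=None, cohort_size=cohort.size,
                            n_contributing=len(recorded),
                            n_missing_outcome=len(days) - len(recorded),
                            low_evidence=cohort.low_evidence)
    if not recorded:
        result.flags.append("no_evidence")
        return result
    result.mean_days = float(mean(recorded))
    return result


def qol_summary(cohort: TwinCohort, db: RWEDatabase) -> EndpointResult:
    """Comparative quality-of-life summary of the twin cohort.

    The cohort's QLQ-C30 global-health scores are binned into tertiles around
    the cohort median (worse / typical / better); the full location summary is
    carried alongside for display.
    """
    values = [db.case(cid).qlq_c30_global for cid in cohort.case_ids]
    recorded = sorted(v for v in values if v is not None)
    result = EndpointResult(endpoint="qol", stage=None, cohort_size=cohort.size,
                            n_contributing=len(recorded),
                            n_missing_outcome=len(values) - len(recorded),
                            low_evidence=cohort.low_evidence)
    if not recorded:
        result.flags.append("no_evidence")
        result.distribution = {}
        return result
    n = len(recorded)
    lower = recorded[max(0, n // 3 - 1)] if n >= 3 else recorded[0]
    upper = recorded[min(n - 1, (2 * n) // 3)] if n >= 3 else recorded[-1]
    bins = {b: 0 for b in QOL_BINS}
    for v in recorded:
        if v <= lower:
            bins["worse_than_typical"] += 1
        elif v > upper:
            bins["better_than_typical"] += 1
        else:
            bins["typical"] += 1
    result.distribution = {b: bins[b] / n for b in QOL_BINS if bins[b] > 0}
    best = max(result.distribution.values())
    result.headline_state = next(b for b in QOL_BINS if result.distribution.get(b) == best)
    result.summary = {"median": float(median(recorded)), "mean": float(mean(recorded)),
                      "tertile_low": float(lower), "tertile_high": float(upper)}
    return result


def infer_warnings(profile: PatientProfile, regimen: Regimen) -> list[str]:
    """Messages of every warning rule whose trigger is YES on the profile.

    Unknown triggers (missing labs) emit nothing — a warning asserts evidence,
    not suspicion.
    """
    out = []
    for rule in regimen.warning_rules:
        if rule.triggered(profile) is TriState.YES:
            out.append(rule.message)
    return out


# ---------------------------------------------------------------------------
# Full assessment
# ---------------------------------------------------------------------------

@dataclass
class OptionAssessment:
    regimen_id: str
    display: str
    includes_asct: bool
    maintenance_options: tuple[str, ...]
    cpg_label: str
    endpoint_results: list[EndpointResult]
    warnings: list[str]

    def to_jsonable(self) -> dict:
        return {
            "regimen_id": self.regimen_id, "display": self.display,
            "includes_asct": self.includes_asct,
            "maintenance_options": list(self.maintenance_options),
            "cpg_label": self.cpg_label,
            "endpoint_results": [r.to_jsonable() for r in self.endpoint_results],
            "warnings": list(self.warnings),
        }

    @classmethod
    def from_jsonable(cls, data: dict) -> "OptionAssessment":
        return cls(regimen_id=data["regimen_id"], display=data["display"],
                   includes_asct=data["includes_asct"],
                   maintenance_options=tuple(data["maintenance_options"]),
                   cpg_label=data["cpg_label"],
                   endpoint_results=[EndpointResult.from_jsonable(r) for r in data["endpoint_results"]],
                   warnings=list(data["warnings"]))


@dataclass
class AssessmentReport:
    """The instantiation output: neutral, provenance-stamped, never ranked.

    Options are ordered by regimen id; the schema deliberately has no score
    or rank field across regimens.
    """

    patient_id: str
    therapy_line: int
    features: SimilarityFeatures
    n_observed_factors: int
    n_operators: int
    options: list[OptionAssessment]
    conflicts: list[Conflict]
    metadata: dict

    def to_jsonable(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "patient_id": self.patient_id,
            "therapy_line": self.therapy_line,
            "features": self.features.to_jsonable(),
            "stratification_trace": {"n_observed_factors": self.n_observed_factors,
                                     "n_operators": self.n_operators},
            "options": [o.to_jsonable() for o in self.options],
            "conflicts": [{"regimen_id": c.regimen_id, "reason": c.reason} for c in self.conflicts],
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_jsonable(cls, data: dict) -> "AssessmentReport":
        version = data.get("schema_version")
        if version != REPORT_SCHEMA_VERSION:
            raise ValueError(f"unsupported report schema version {version!r}")
        feats = data["features"]
        features = SimilarityFeatures(
            fitness=feats["fitness"],
            high_risk_cytogenetics=TriState(feats["high_risk_cytogenetics"]),
            iss_stage=feats["iss_stage"],
        )
        return cls(
            patient_id=data["patient_id"], therapy_line=data["therapy_line"],
            features=features,
            n_observed_factors=data["stratification_trace"]["n_observed_factors"],
            n_operators=data["stratification_trace"]["n_operators"],
            options=[OptionAssessment.from_jsonable(o) for o in data["options"]],
            conflicts=[Conflict(c["regimen_id"], c["reason"]) for c in data["conflicts"]],
            metadata=dict(data["metadata"]),
        )


def _endpoint_results_for(regimen: Regimen, features: SimilarityFeatures,
                          db: RWEDatabase, profiles: dict[str, SimilarityProfile],
                          therapy_line: int) -> list[EndpointResult]:
    results: list[EndpointResult] = []
    for endpoint in ENDPOINTS:
        if endpoint == "em" and not regimen.includes_asct:
            continue  # early mortality is defined relative to the transplant
        profile_cfg = profiles[endpoint]
        try:
            cohort = match_cohort(features, db, profile_cfg, regimen.id, therapy_line)
        except InsufficientCharacterizationError as exc:
            results.append(EndpointResult(endpoint=endpoint, stage=None, cohort_size=0,
                                          n_contributing=0, n_missing_outcome=0,
                                          flags=[f"insufficient_characterization:{exc.measure}"]))
            continue
        if endpoint == "remission":
            stages = [POST_INDUCTION, POST_ASCT] if regimen.includes_asct else [POST_INDUCTION]
            for stage in stages:
                results.append(endpoint_distribution(cohort, db, "remission", stage))
        elif endpoint in ("ae", "em"):
            results.append(endpoint_distribution(cohort, db, endpoint))
        elif endpoint == "ttnt":
            results.append(ttnt_mean(cohort, db))
        elif endpoint == "qol":
            results.append(qol_summary(cohort, db))
    return results


def assess(profile: PatientProfile, db: RWEDatabase,
           profiles: dict[str, SimilarityProfile], kb, regimens: dict[str, Regimen],
           seed: int | None = None) -> AssessmentReport:
    """End-to-end instantiation: characterize, select options, simulate outcomes.

    ``kb`` is a :class:`mmdt.reference.ReferenceKB` (network + operator
    registry).  Deterministic given (inputs, configuration, seed).
    """
    features, trace = derive_similarity_features(profile.observations, kb.registry, kb.network)
    n_observed, n_operators = trace_summary(trace)
    options, conflicts = candidate_options(features, profile, regimens)

    assessments = []
    for regimen in options:
        assessments.append(OptionAssessment(
            regimen_id=regimen.id,
            display=regimen.display,
            includes_asct=regimen.includes_asct,
            maintenance_options=regimen.maintenance_options,
            cpg_label=regimen.cpg_status,
            endpoint_results=_endpoint_results_for(regimen, features, db, profiles,
                                                   profile.therapy_line),
            warnings=infer_warnings(profile, regimen),
        ))

    metadata = {
        "db_id": db.db_id,
        "db_hash": db.content_hash(),
        "profiles_hash": profiles_hash(profiles),
        "n_cases": len(db),
        "seed": seed,
    }
    return AssessmentReport(
        patient_id=profile.patient_id,
        therapy_line=profile.therapy_line,
        features=features,
        n_observed_factors=n_observed,
        n_operators=n_operators,
        options=assessments,
        conflicts=conflicts,
        metadata=metadata,
    )
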