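"""RWE query side: endpoint-specific twin-cohort identification.

Each endpoint owns a *similarity profile* naming the derived measures a
retrospective case must match exactly (no distance metric): remission, time
to next treatment and early mortality constrain all three measures; quality
of life and adverse events constrain fitness only.  Cases whose constrained
measure cannot be derived are excluded — missing data never counts as a
match.  Cohorts below the configured minimum size are flagged low-evidence,
never silently relaxed.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import dataclass, field, fields
from importlib import resources

import pandas as pd
import yaml

from . import scores
from .scores import SimilarityFeatures
from .tristate import TriState, UNKNOWN

ENDPOINTS = ("remission", "ttnt", "qol", "ae", "em")
MEASURES = ("fitness", "high_risk_cytogenetics", "iss_stage")

_MARKERS = scores.CYTOGENETIC_MARKERS


class InsufficientCharacterizationError(ValueError):
    def __init__(self, measure: str):
        super().__init__(f"insufficient patient characterization: similarity measure "
                         f"{measure!r} is unknown but constrained by the profile")
        self.measure = measure


@dataclass(frozen=True)
class SimilarityProfile:
    endpoint: str
    constrained_measures: frozenset[str]
    min_cohort_size: int = 10

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        unknown = self.constrained_measures - set(MEASURES)
        if unknown:
            raise ValueError(f"unknown similarity measures {sorted(unknown)}")


def load_profiles(path=None) -> dict[str, SimilarityProfile]:
    """Load similarity profiles from YAML; with no path, the shipped defaults."""
    if path is None:
        with resources.files("mmdt.data").joinpath("similarity_profiles.yaml").open("r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    min_size = int(raw.get("min_cohort_size", 10))
    out = {}
    for endpoint, cfg in raw["profiles"].items():
        out[endpoint] = SimilarityProfile(
            endpoint=endpoint,
            constrained_measures=frozenset(cfg["constrained"]),
            min_cohort_size=int(cfg.get("min_cohort_size", min_size)),
        )
    missing = set(ENDPOINTS) - set(out)
    if missing:
        raise ValueError(f"profiles missing endpoints {sorted(missing)}")
    return out


def default_profiles() -> dict[str, SimilarityProfile]:
    return load_profiles(None)


# ---------------------------------------------------------------------------
# Retrospective cases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RWECase:
    """One retrospective first-line case with covariates and recorded outcomes."""

    case_id: str
    regimen_id: str
    therapy_line: int = 1
    age: float | None = None
    ecog: int | None = None
    cci: int | None = None
    t_4_14: str | None = None       # "yes" | "no" | None (not documented)
    t_14_16: str | None = None
    del_17p: str | None = None
    gain_1q21: str | None = None
    t_14_20: str | None = None
    albumin: float | None = None
    b2m: float | None = None
    maintenance_substance: str | None = None
    remission_post_induction: str | None = None
    remission_post_asct: str | None = None
    ttnt_days: float | None = None
    ae_grade3plus: bool | None = None
    qlq_c30_global: float | None = None
    qlq_my20_disease_symptoms: float | None = None
    qlq_my20_side_effects: float | None = None
    early_mortality: bool | None = None

    def __post_init__(self) -> None:
        if self.ttnt_days is not None and self.ttnt_days <= 0:
            raise ValueError(f"case {self.case_id}: ttnt_days must be positive")
        for stage in ("remission_post_induction", "remission_post_asct"):
            value = getattr(self, stage)
            if value is not None and value not in scores.REMISSION_CATEGORIES:
                raise ValueError(f"case {self.case_id}: illegal remission category {value!r}")

    def marker_state(self, marker: str) -> TriState:
        raw = getattr(self, marker)
        if raw is None:
            return UNKNOWN
        return TriState.YES if raw == "yes" else TriState.NO


def derive_case_features(case: RWECase) -> SimilarityFeatures:
    """Stratify one case with the same rule pack applied to patients."""
    iss = scores.iss_stage(case.albumin, case.b2m)
    hrc = scores.high_risk_cytogenetics(*(case.marker_state(m) for m in _MARKERS))
    fit = scores.fitness(age=case.age, ecog=case.ecog, cci=case.cci)
    return SimilarityFeatures(fitness=fit, high_risk_cytogenetics=hrc, iss_stage=iss)


_CSV_COLUMNS = [f.name for f in fields(RWECase)]
_BOOL_COLUMNS = ("ae_grade3plus", "early_mortality")
_INT_COLUMNS = ("therapy_line", "ecog", "cci")
_FLOAT_COLUMNS = ("age", "albumin", "b2m", "ttnt_days", "qlq_c30_global",
                  "qlq_my20_disease_symptoms", "qlq_my20_side_effects")


@dataclass
class RWEDatabase:
    """A set of retrospective cases plus a per-load feature cache."""

    cases: list[RWECase]
    db_id: str = "rwe"
    _features: dict[str, SimilarityFeatures] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.cases)

    def case(self, case_id: str) -> RWECase:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise KeyError(case_id)

    def features(self, case: RWECase) -> SimilarityFeatures:
        cached = self._features.get(case.case_id)
        if cached is None:
            cached = derive_case_features(case)
            self._features[case.case_id] = cached
        return cached

    # -- serialization -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cases:
            row = {}
            for name in _CSV_COLUMNS:
                value = getattr(c, name)
                if name in _BOOL_COLUMNS and value is not None:
                    value = "yes" if value else "no"
                row[name] = "" if value is None else value
            rows.append(row)
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, db_id: str = "rwe") -> "RWEDatabase":
        cases = []
        for _, row in frame.iterrows():
            kwargs = {}
            # registries that record the death date instead of the endpoint:
            # classify with the 100-day post-transplant window
            death_days = row.get("death_days_after_asct", "")
            if death_days not in ("", None) and not row.get("early_mortality", ""):
                state = scores.early_mortality_from_days(float(death_days))
                row = row.copy()
                row["early_mortality"] = state.value
            for name in _CSV_COLUMNS:
                raw = row.get(name, "")
                if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
                    kwargs[name] = None
                    continue
                if name in _BOOL_COLUMNS:
                    kwargs[name] = str(raw).strip().lower() in ("yes", "true", "1")
                elif name in _INT_COLUMNS:
                    kwargs[name] = int(float(raw))
                elif name in _FLOAT_COLUMNS:
                    kwargs[name] = float(raw)
                else:
                    kwargs[name] = str(raw)
            if kwargs["therapy_line"] is None:
                kwargs["therapy_line"] = 1
            cases.append(RWECase(**kwargs))
        return cls(cases=cases, db_id=db_id)

    @classmethod
    def read_csv(cls, path, db_id: str | None = None) -> "RWEDatabase":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        return cls.from_frame(frame, db_id=db_id or str(path))

    def content_hash(self) -> str:
        buffer = _io.StringIO()
        self.to_frame().to_csv(buffer, index=False, lineterminator="\n")
        return hashlib.sha256(buffer.getvalue().encode("utf-8")).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Twin cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwinCohort:
    endpoint: str
    case_ids: tuple[str, ...]
    matched_on: dict
    regimen_id: str
    therapy_line: int
    low_evidence: bool

    @property
    def size(self) -> int:
        return len(self.case_ids)

    def to_jsonable(self) -> dict:
        return {"endpoint": self.endpoint, "size": self.size,
                "matched_on": self.matched_on, "regimen_id": self.regimen_id,
                "therapy_line": self.therapy_line, "low_evidence": self.low_evidence}


def match_cohort(features: SimilarityFeatures, db: RWEDatabase, profile: SimilarityProfile,
                 regimen_id: str, therapy_line: int = 1) -> TwinCohort:
    """Identify the endpoint's twin cohort by exact match on constrained measures.

    Deterministic: membership is a pure filter and ordering is by case id.
    Raises :class:`InsufficientCharacterizationError` when the patient's own
    constrained measure is unknown; an undersized cohort is flagged, not an
    error.
    """
    patient_values = {}
    for measure in sorted(profile.constrained_measures):
        value = features.get(measure)
        if value is None:
            raise InsufficientCharacterizationError(measure)
        patient_values[measure] = value

    matched = []
    for case in db.cases:
        if case.regimen_id != regimen_id or case.therapy_line != therapy_line:
            continue
        case_features = db.features(case)
        ok = True
        for measure, wanted in patient_values.items():
            if case_features.get(measure) != wanted:
                ok = False
                break
        if ok:
            matched.append(case.case_id)
    matched.sort()
    return TwinCohort(
        endpoint=profile.endpoint,
        case_ids=tuple(matched),
        matched_on=dict(patient_values),
        regimen_id=regimen_id,
        therapy_line=therapy_line,
        low_evidence=len(matched) < profile.min_cohort_size,
    )


def profiles_hash(profiles: dict[str, SimilarityProfile]) -> str:
    canon = {e: {"constrained": sorted(p.constrained_measures), "min": p.min_cohort_size}
             for e, p in sorted(profiles.items())}
    return hashlib.sha256(json.dumps(canon, sort_keys=True).encode()).hexdigest()[:16]
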