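"""Myeloma operator pack: staging, diagnostic criteria, comorbidity and fitness.

Pure rule functions over possibly-missing inputs (``None`` means not
documented).  Tri-state outputs follow the asymmetric missing-data stance:
presence of a criterion can be inferred from partial data, absence only from
complete data.  All thresholds ship as overridable configuration
(``data/thresholds.json``); the defaults follow the published international
criteria (ISS albumin/β2-microglobulin cutoffs, CRAB and SLiM biomarker
thresholds, the standard Charlson weights and the standard
Karnofsky→ECOG mapping).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from importlib import resources

from .tristate import NO, UNKNOWN, YES, TriState, tri_or


class DomainError(ValueError):
    """Input outside its clinical domain (negative lab value, KPS > 100, ...)."""


def _load_data(name: str) -> dict:
    with resources.files("mmdt.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return json.load(fh)


THRESHOLDS: dict = _load_data("thresholds.json")
CHARLSON_WEIGHTS: dict[str, int] = _load_data("charlson_weights.json")

FITNESS_CLASSES = ("fit", "intermediate", "frail")
ISS_STAGES = (1, 2, 3)

REMISSION_CATEGORIES = ("sCR", "CR", "VGPR", "PR", "SD", "PD")


def _check_non_negative(**values: float | None) -> None:
    for name, v in values.items():
        if v is not None and v < 0:
            raise DomainError(f"{name} must be non-negative, got {v}")


# ---------------------------------------------------------------------------
# Staging
# ---------------------------------------------------------------------------

def iss_stage(albumin: float | None, b2m: float | None, thresholds: dict | None = None) -> int | None:
    """International Staging System from serum albumin (g/dl) and β2M (mg/L).

    Stage I requires β2M < 3.5 mg/L *and* albumin ≥ 3.5 g/dl; stage III is
    β2M ≥ 5.5 mg/L; stage II is everything in between.  Partial data resolves
    only what it decides: without β2M no stage is decidable; with
    β2M < 3.5 but albumin missing, stage I vs II is undecidable and ``None``
    is returned, while β2M in [3.5, 5.5) forces stage II on its own.
    """
    t = (thresholds or THRESHOLDS)["iss"]
    _check_non_negative(albumin=albumin, b2m=b2m)
    if b2m is None:
        return None
    if b2m >= t["b2m_high"]:
        return 3
    if b2m >= t["b2m_low"]:
        return 2
    if albumin is None:
        return None
    return 1 if albumin >= t["albumin"] else 2


# ---------------------------------------------------------------------------
# CRAB components and biomarker (SLiM) criteria
# ---------------------------------------------------------------------------

def anemia(hemoglobin: float | None, lln: float | None = None, thresholds: dict | None = None) -> TriState:
    t = (thresholds or THRESHOLDS)["anemia"]
    lln = t["lln"] if lln is None else lln
    _check_non_negative(hemoglobin=hemoglobin)
    if hemoglobin is None:
        return UNKNOWN
    return TriState.from_bool(hemoglobin < t["hb_abs"] or hemoglobin < lln - t["lln_delta"])


def hypercalcemia(calcium: float | None, uln: float | None = None, thresholds: dict | None = None) -> TriState:
    t = (thresholds or THRESHOLDS)["hypercalcemia"]
    uln = t["uln"] if uln is None else uln
    _check_non_negative(calcium=calcium)
    if calcium is None:
        return UNKNOWN
    return TriState.from_bool(calcium > t["ca_abs"] or calcium > uln + t["uln_delta"])


def renal_insufficiency(creatinine: float | None, egfr: float | None = None,
                        thresholds: dict | None = None) -> TriState:
    """Renal end-organ damage: creatinine > 2.0 mg/dl or eGFR < 40 ml/min.

    Creatinine is the primary criterion (eGFR is itself creatinine-derived):
    with creatinine documented the output is decided, an additionally low eGFR
    can only confirm; only when both are absent is the state unknown.
    """
    t = (thresholds or THRESHOLDS)["renal"]
    _check_non_negative(creatinine=creatinine, egfr=egfr)
    if creatinine is None and egfr is None:
        return UNKNOWN
    hit = (creatinine is not None and creatinine > t["creatinine"]) or \
          (egfr is not None and egfr < t["egfr"])
    return TriState.from_bool(hit)


def bone_lesions(count: float | None, thresholds: dict | None = None) -> TriState:
    t = (thresholds or THRESHOLDS)["bone"]
    _check_non_negative(count=count)
    if count is None:
        return UNKNOWN
    return TriState.from_bool(count >= t["min_lesions"])


def crab(anemia_state: TriState, renal_state: TriState, hypercalcemia_state: TriState,
         bone_state: TriState) -> TriState:
    """End-organ damage: disjunctive tri-state OR over the four criteria."""
    return tri_or((anemia_state, renal_state, hypercalcemia_state, bone_state))


def slim(plasma_cell_pct: float | None, flc_ratio: float | None,
         mri_focal_lesions: float | None, thresholds: dict | None = None) -> TriState:
    """Biomarker criteria: ≥60% clonal plasma cells, involved/uninvolved FLC
    ratio ≥100, or >1 focal lesion on MRI."""
    t = (thresholds or THRESHOLDS)["slim"]
    _check_non_negative(plasma_cell_pct=plasma_cell_pct, flc_ratio=flc_ratio,
                        mri_focal_lesions=mri_focal_lesions)

    def criterion(value: float | None, hit: bool) -> TriState:
        return UNKNOWN if value is None else TriState.from_bool(hit)

    return tri_or((
        criterion(plasma_cell_pct, plasma_cell_pct is not None and plasma_cell_pct >= t["plasma_cell_pct"]),
        criterion(flc_ratio, flc_ratio is not None and flc_ratio >= t["flc_ratio"]),
        criterion(mri_focal_lesions, mri_focal_lesions is not None and mri_focal_lesions > t["mri_focal_lesions"]),
    ))


CYTOGENETIC_MARKERS = ("t_4_14", "t_14_16", "del_17p", "gain_1q21", "t_14_20")


def high_risk_cytogenetics(t_4_14: TriState, t_14_16: TriState, del_17p: TriState,
                           gain_1q21: TriState, t_14_20: TriState) -> TriState:
    """Any one of the five aberrations justifies the high-risk label; its
    absence requires all five to be documented negative."""
    return tri_or((t_4_14, t_14_16, del_17p, gain_1q21, t_14_20))


# ---------------------------------------------------------------------------
# Comorbidity, performance and the composite fitness measure
# ---------------------------------------------------------------------------

def cci_score(conditions: list[str] | None) -> int | None:
    """Unadjusted Charlson comorbidity sum over coded condition flags.

    ``None`` (no comorbidity assessment documented) yields unknown; an empty
    list is an explicit assessment scoring 0.  Unknown condition codes raise.
    """
    if conditions is None:
        return None
    total = 0
    for cond in conditions:
        key = cond.strip().lower().replace(" ", "_")
        if key not in CHARLSON_WEIGHTS:
            raise DomainError(f"unknown Charlson condition {cond!r}")
        total += CHARLSON_WEIGHTS[key]
    return total


def ecog_from_karnofsky(kps: float | None) -> int | None:
    """Standard Karnofsky→ECOG mapping (90–100→0, 70–80→1, 50–60→2,
    30–40→3, 10–20→4; below 10 maps to 5)."""
    if kps is None:
        return None
    if not 0 <= kps <= 100:
        raise DomainError(f"Karnofsky score must lie in [0, 100], got {kps}")
    for threshold, grade in ((90, 0), (70, 1), (50, 2), (30, 3), (10, 4)):
        if kps >= threshold:
            return grade
    return 5


def _fitness_points(age: float, ecog_pts: int | None, cci_pts: int | None,
                    t: dict) -> tuple[int, list[tuple[int, int]]]:
    """Known points plus (low, high) bounds of each missing component."""
    a_lo, a_hi = t["age_bands"]
    base = 0 if age <= a_lo else (1 if age <= a_hi else 2)
    bounds = []
    known = base
    for pts in (ecog_pts, cci_pts):
        if pts is None:
            bounds.append((0, 2))
        else:
            known += pts
    return known, bounds


def _fitness_class(points: int, t: dict) -> str:
    lo, hi = t["class_bands"]
    if points <= lo:
        return "fit"
    if points <= hi:
        return "intermediate"
    return "frail"


def fitness(age: float | None, ecog: int | None = None, kps: float | None = None,
            cci: int | None = None, thresholds: dict | None = None) -> str | None:
    """Composite treatment-tolerance class from age, performance status and
    comorbidity burden.

    Points: age ≤65→0, 66–75→1, >75→2; ECOG 0–1→0, 2→1, ≥3→2 (Karnofsky is
    the documented proxy when ECOG is missing); CCI ≤1→0, 2–3→1, ≥4→2.
    Total ≤1 → fit, 2–3 → intermediate, ≥4 → frail.  Age is mandatory.  With
    a missing component the class is reported only when the optimistic and
    pessimistic completions agree; otherwise the measure stays unknown.
    """
    t = (thresholds or THRESHOLDS)["fitness"]
    if age is None:
        return None
    _check_non_negative(age=age)
    if ecog is None and kps is not None:
        ecog = ecog_from_karnofsky(kps)

    e_lo, e_hi = t["ecog_bands"]  # default [1, 2]: ECOG <=1 -> 0, ==2 -> 1, >=3 -> 2
    ecog_pts = None if ecog is None else (0 if ecog <= e_lo else (1 if ecog <= e_hi else 2))
    c_lo, c_hi = t["cci_bands"]
    cci_pts = None if cci is None else (0 if cci <= c_lo else (1 if cci <= c_hi else 2))

    known, missing_bounds = _fitness_points(age, ecog_pts, cci_pts, t)
    optimistic = known + sum(lo for lo, _ in missing_bounds)
    pessimistic = known + sum(hi for _, hi in missing_bounds)
    cls_opt = _fitness_class(optimistic, t)
    cls_pess = _fitness_class(pessimistic, t)
    return cls_opt if cls_opt == cls_pess else None


def fitness_bruteforce(age: float | None, ecog: int | None = None, kps: float | None = None,
                       cci: int | None = None, thresholds: dict | None = None) -> str | None:
    """Independent oracle for the bounds logic: enumerate every completion of
    the missing components and return the class only if all agree."""
    t = (thresholds or THRESHOLDS)["fitness"]
    if age is None:
        return None
    if ecog is None and kps is not None:
        ecog = ecog_from_karnofsky(kps)
    ecog_options = [ecog] if ecog is not None else [0, 2, 3]      # spans all point values
    cci_options = [cci] if cci is not None else [0, 2, 4]
    classes = set()
    for e, c in itertools.product(ecog_options, cci_options):
        e_lo, e_hi = t["ecog_bands"]
        c_lo, c_hi = t["cci_bands"]
        a_lo, a_hi = t["age_bands"]
        pts = (0 if age <= a_lo else 1 if age <= a_hi else 2) \
            + (0 if e <= e_lo else 1 if e <= e_hi else 2) \
            + (0 if c <= c_lo else 1 if c <= c_hi else 2)
        classes.add(_fitness_class(pts, t))
    return classes.pop() if len(classes) == 1 else None


# ---------------------------------------------------------------------------
# Similarity features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityFeatures:
    """The three patient-stratification measures used for twin-cohort matching.

    ``fitness`` and ``iss_stage`` use ``None`` for unknown; high-risk
    cytogenetics is genuinely three-valued.
    """

    fitness: str | None
    high_risk_cytogenetics: TriState
    iss_stage: int | None

    def __post_init__(self) -> None:
        if self.fitness is not None and self.fitness not in FITNESS_CLASSES:
            raise DomainError(f"illegal fitness class {self.fitness!r}")
        if self.iss_stage is not None and self.iss_stage not in ISS_STAGES:
            raise DomainError(f"illegal ISS stage {self.iss_stage!r}")

    def get(self, measure: str):
        value = getattr(self, measure)
        if measure == "high_risk_cytogenetics":
            return None if value is UNKNOWN else value.value
        return value

    def to_jsonable(self) -> dict:
        return {
            "fitness": self.fitness,
            "high_risk_cytogenetics": self.high_risk_cytogenetics.value,
            "iss_stage": self.iss_stage,
        }


# ---------------------------------------------------------------------------
# Early-mortality window
# ---------------------------------------------------------------------------

def early_mortality_from_days(death_days_after_asct: float | None,
                              window_days: int = 100) -> TriState:
    """Death within the 100-day post-transplant window (boundary inclusive)."""
    if death_days_after_asct is None:
        return NO  # no recorded death in follow-up
    _check_non_negative(death_days_after_asct=death_days_after_asct)
    return YES if death_days_after_asct <= window_days else NO
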