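"""Synthetic first-line RWE databases with known generative structure.

Stands in for the access-restricted registry data the outcome simulator is
designed to query.  Covariates (age, performance status, comorbidity burden,
cytogenetics, albumin, β2-microglobulin) are drawn from plausible myeloma
magnitudes; treatment assignment follows fitness (transplant-eligible
patients receive an induction + ASCT strategy); outcomes are generated
conditionally on the SAME three similarity measures used for matching, so
exact matching is correctly specified and the matched-cohort distributions
are recoverable.  Every conditional distribution actually used is recorded
in a ground-truth sidecar for recovery testing.

Default parameters are synthetic test-bed magnitudes chosen for test power,
not clinical estimates.  A config switch (``unmatched_covariate_effect``)
adds an outcome effect not visible to matching, to demonstrate residual
confounding.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.stats import truncnorm

from . import scores
from .matching import RWECase, RWEDatabase
from .outcomes import POST_ASCT, POST_INDUCTION, Regimen
from .tristate import TriState

MAINTENANCE_SUBSTANCES = ("bortezomib", "lenalidomide", "ixazomib")

#: remission categories ordered worst -> best on the latent scale
_ORDERED = ("PD", "SD", "PR", "VGPR", "CR", "sCR")

_MARKERS = scores.CYTOGENETIC_MARKERS

_MASKABLE = ("age", "ecog", "cci", "albumin", "b2m",
             "t_4_14", "t_14_16", "del_17p", "gain_1q21", "t_14_20")


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    n_cases: int = 5000
    seed: int = 0

    # covariates
    age_mean: float = 68.0
    age_sd: float = 9.0
    age_min: float = 35.0
    age_max: float = 90.0
    ecog_probs: tuple[float, ...] = (0.35, 0.35, 0.2, 0.08, 0.02)
    cci_lambda: float = 1.2
    marker_prevalence: dict = field(default_factory=lambda: {
        "t_4_14": 0.12, "t_14_16": 0.03, "del_17p": 0.10,
        "gain_1q21": 0.30, "t_14_20": 0.02,
    })
    albumin_mean: float = 3.7
    albumin_sd: float = 0.6
    b2m_meanlog: float = math.log(3.5)
    b2m_sdlog: float = 0.5

    # treatment assignment policy
    fit_policy: dict = field(default_factory=lambda: {"VRD_ASCT": 0.6, "VCD_ASCT": 0.4})
    nonfit_policy: dict = field(default_factory=lambda: {"VRD": 0.7, "VCD": 0.3})

    # ordinal remission model (latent logistic scale)
    remission_cutpoints: tuple[float, ...] = (-4.94, -3.83, -2.49, 2.30, 4.01)
    regimen_effect: dict = field(default_factory=lambda: {
        "VRD": 0.7, "VRD_ASCT": 0.7, "VCD": 0.0, "VCD_ASCT": 0.0})
    post_asct_shift: float = 0.9
    hrc_penalty: float = 0.8
    iss_penalty: float = 0.35
    fitness_penalty: dict = field(default_factory=lambda: {
        "fit": 0.0, "intermediate": 0.2, "frail": 0.5})

    # time to next treatment (lognormal days)
    ttnt_base_meanlog: float = math.log(720.0)
    ttnt_sdlog: float = 0.45
    ttnt_vrd_shift: float = 0.25
    ttnt_asct_shift: float = 0.35
    ttnt_hrc_shift: float = -0.30
    ttnt_iss_shift: float = -0.15
    ttnt_nonfit_shift: float = -0.20

    # adverse events / early mortality / quality of life
    ae_logit_base: float = -1.5
    ae_fitness_shift: dict = field(default_factory=lambda: {
        "fit": 0.0, "intermediate": 0.5, "frail": 1.0})
    ae_asct_shift: float = 0.6
    em_base: float = 0.02
    em_nonfit_multiplier: float = 3.0
    qol_mean: float = 62.0
    qol_sd: float = 18.0
    qol_fitness_shift: dict = field(default_factory=lambda: {
        "fit": 0.0, "intermediate": -4.0, "frail": -8.0})
    my20_mean: float = 30.0
    my20_sd: float = 15.0

    # residual-confounding demonstration: effect of an unmatched covariate
    unmatched_covariate_effect: float = 0.0

    # missingness and curation-filter injections
    missingness: dict = field(default_factory=lambda: {f: 0.0 for f in _MASKABLE})
    n_off_cpg: int = 0
    n_incomplete: int = 0
    off_cpg_regimen_id: str = "MP"

    def validate(self) -> list[str]:
        errors = []
        if self.n_cases < 1:
            errors.append("n_cases must be >= 1")
        if abs(sum(self.ecog_probs) - 1.0) > 1e-9:
            errors.append("ecog_probs must sum to 1")
        for name, policy in (("fit_policy", self.fit_policy), ("nonfit_policy", self.nonfit_policy)):
            if abs(sum(policy.values()) - 1.0) > 1e-9:
                errors.append(f"{name} probabilities must sum to 1")
        for m, p in self.marker_prevalence.items():
            if not 0.0 <= p <= 1.0:
                errors.append(f"marker prevalence {m} outside [0, 1]")
        for f, r in self.missingness.items():
            if not 0.0 <= r <= 1.0:
                errors.append(f"missingness rate {f} outside [0, 1]")
            if f not in _MASKABLE:
                errors.append(f"missingness configured for unknown field {f!r}")
        if self.n_off_cpg + self.n_incomplete > self.n_cases:
            errors.append("injected bad cases exceed n_cases")
        if list(self.remission_cutpoints) != sorted(self.remission_cutpoints):
            errors.append("remission_cutpoints must be non-decreasing")
        return errors

    def to_jsonable(self) -> dict:
        out = asdict(self)
        out["ecog_probs"] = list(self.ecog_probs)
        out["remission_cutpoints"] = list(self.remission_cutpoints)
        return out


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


# ---------------------------------------------------------------------------
# Generative conditionals (shared by the sampler and the ground-truth sidecar)
# ---------------------------------------------------------------------------

def remission_probs(config: GeneratorConfig, regimen_id: str, stage: str,
                    fitness: str, hrc_yes: bool, iss: int,
                    unmatched: float = 0.0) -> dict[str, float]:
    eta = (config.regimen_effect[regimen_id]
           + (config.post_asct_shift if stage == POST_ASCT else 0.0)
           - (config.hrc_penalty if hrc_yes else 0.0)
           - config.iss_penalty * (iss - 1)
           - config.fitness_penalty[fitness]
           + unmatched)
    cum = [_sigmoid(c - eta) for c in config.remission_cutpoints] + [1.0]
    probs = {}
    previous = 0.0
    for category, upper in zip(_ORDERED, cum):
        probs[category] = upper - previous
        previous = upper
    return {c: probs[c] for c in scores.REMISSION_CATEGORIES}


def ttnt_meanlog(config: GeneratorConfig, regimen_id: str, fitness: str,
                 hrc_yes: bool, iss: int) -> float:
    return (config.ttnt_base_meanlog
            + (config.ttnt_vrd_shift if regimen_id.startswith("VRD") else 0.0)
            + (config.ttnt_asct_shift if regimen_id.endswith("_ASCT") else 0.0)
            + (config.ttnt_hrc_shift if hrc_yes else 0.0)
            + config.ttnt_iss_shift * (iss - 1)
            + (config.ttnt_nonfit_shift if fitness != "fit" else 0.0))


def ttnt_mean_days(config: GeneratorConfig, regimen_id: str, fitness: str,
                   hrc_yes: bool, iss: int) -> float:
    return math.exp(ttnt_meanlog(config, regimen_id, fitness, hrc_yes, iss)
                    + 0.5 * config.ttnt_sdlog ** 2)


def ae_prob(config: GeneratorConfig, fitness: str, includes_asct: bool) -> float:
    return _sigmoid(config.ae_logit_base + config.ae_fitness_shift[fitness]
                    + (config.ae_asct_shift if includes_asct else 0.0))


def em_prob(config: GeneratorConfig, fitness: str) -> float:
    p = config.em_base * (config.em_nonfit_multiplier if fitness != "fit" else 1.0)
    return min(p, 1.0)


def ground_truth(config: GeneratorConfig) -> dict:
    """Every conditional distribution the sampler uses, keyed by condition."""
    truth: dict = {"config": config.to_jsonable(), "remission": {}, "ttnt_mean_days": {},
                   "ae_prob": {}, "em_prob": {}, "qol_mean": {}}
    regimens = sorted(set(config.fit_policy) | set(config.nonfit_policy))
    for regimen_id in regimens:
        stages = [POST_INDUCTION, POST_ASCT] if regimen_id.endswith("_ASCT") else [POST_INDUCTION]
        for stage in stages:
            for fitness in scores.FITNESS_CLASSES:
                for hrc in ("no", "yes"):
                    for iss in scores.ISS_STAGES:
                        key = f"{regimen_id}|{stage}|{fitness}|hrc_{hrc}|iss{iss}"
                        truth["remission"][key] = remission_probs(
                            config, regimen_id, stage, fitness, hrc == "yes", iss)
        for fitness in scores.FITNESS_CLASSES:
            for hrc in ("no", "yes"):
                for iss in scores.ISS_STAGES:
                    key = f"{regimen_id}|{fitness}|hrc_{hrc}|iss{iss}"
                    truth["ttnt_mean_days"][key] = ttnt_mean_days(
                        config, regimen_id, fitness, hrc == "yes", iss)
            truth["ae_prob"][f"{regimen_id}|{fitness}"] = ae_prob(
                config, fitness, regimen_id.endswith("_ASCT"))
            if regimen_id.endswith("_ASCT"):
                truth["em_prob"][f"{regimen_id}|{fitness}"] = em_prob(config, fitness)
    for fitness in scores.FITNESS_CLASSES:
        truth["qol_mean"][fitness] = config.qol_mean + config.qol_fitness_shift[fitness]
    truth["ttnt_sdlog"] = config.ttnt_sdlog
    return truth


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _sample_categorical(rng: np.random.Generator, probs: dict[str, float]) -> str:
    categories = list(probs)
    u = rng.random()
    acc = 0.0
    for c in categories:
        acc += probs[c]
        if u < acc:
            return c
    return categories[-1]


def _truncnorm_draw(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate(config: GeneratorConfig) -> tuple[RWEDatabase, dict]:
    """Draw a synthetic curatable RWE database plus its ground-truth sidecar.

    Identical config (including seed) yields a byte-identical CSV.
    """
    errors = config.validate()
    if errors:
        raise ConfigError("invalid generator config: " + "; ".join(errors))

    rng = np.random.default_rng(config.seed)
    n = config.n_cases

    ages = np.rint(_truncnorm_draw(rng, config.age_mean, config.age_sd,
                                   config.age_min, config.age_max, n)).astype(int)
    ecogs = rng.choice(len(config.ecog_probs), size=n, p=np.asarray(config.ecog_probs))
    ccis = rng.poisson(config.cci_lambda, size=n)
    markers = {m: rng.random(n) < p for m, p in sorted(config.marker_prevalence.items())}
    albumins = np.round(np.clip(rng.normal(config.albumin_mean, config.albumin_sd, n), 0.5, 6.5), 2)
    b2ms = np.round(rng.lognormal(config.b2m_meanlog, config.b2m_sdlog, n), 2)
    unmatched_latent = rng.standard_normal(n) * (1.0 if config.unmatched_covariate_effect else 0.0)

    cases: list[RWECase] = []
    for i in range(n):
        iss = scores.iss_stage(float(albumins[i]), float(b2ms[i]))
        hrc = scores.high_risk_cytogenetics(
            *(TriState.from_bool(bool(markers[m][i])) for m in _MARKERS))
        fit = scores.fitness(age=float(ages[i]), ecog=int(ecogs[i]), cci=int(ccis[i]))
        assert iss is not None and fit is not None  # all covariates drawn complete
        hrc_yes = hrc is TriState.YES

        policy = config.fit_policy if fit == "fit" else config.nonfit_policy
        regimen_id = _sample_categorical(rng, policy)
        includes_asct = regimen_id.endswith("_ASCT")

        unmatched = config.unmatched_covariate_effect * unmatched_latent[i]
        remission_pi = _sample_categorical(
            rng, remission_probs(config, regimen_id, POST_INDUCTION, fit, hrc_yes, iss, unmatched))
        remission_pa = None
        maintenance = None
        em = None
        if includes_asct:
            remission_pa = _sample_categorical(
                rng, remission_probs(config, regimen_id, POST_ASCT, fit, hrc_yes, iss, unmatched))
            maintenance = MAINTENANCE_SUBSTANCES[int(rng.integers(len(MAINTENANCE_SUBSTANCES)))]
            em = bool(rng.random() < em_prob(config, fit))
        ttnt = max(1.0, float(np.rint(rng.lognormal(
            ttnt_meanlog(config, regimen_id, fit, hrc_yes, iss), config.ttnt_sdlog))))
        ae = bool(rng.random() < ae_prob(config, fit, includes_asct))
        qol = float(np.round(np.clip(rng.normal(
            config.qol_mean + config.qol_fitness_shift[fit], config.qol_sd), 0.0, 100.0), 1))
        my20_ds = float(np.round(np.clip(rng.normal(config.my20_mean, config.my20_sd), 0.0, 100.0), 1))
        my20_se = float(np.round(np.clip(rng.normal(config.my20_mean, config.my20_sd), 0.0, 100.0), 1))

        cases.append(RWECase(
            case_id=f"case-{i:05d}", regimen_id=regimen_id, therapy_line=1,
            age=float(ages[i]), ecog=int(ecogs[i]), cci=int(ccis[i]),
            t_4_14="yes" if markers["t_4_14"][i] else "no",
            t_14_16="yes" if markers["t_14_16"][i] else "no",
            del_17p="yes" if markers["del_17p"][i] else "no",
            gain_1q21="yes" if markers["gain_1q21"][i] else "no",
            t_14_20="yes" if markers["t_14_20"][i] else "no",
            albumin=float(albumins[i]), b2m=float(b2ms[i]),
            maintenance_substance=maintenance,
            remission_post_induction=remission_pi,
            remission_post_asct=remission_pa,
            ttnt_days=ttnt, ae_grade3plus=ae,
            qlq_c30_global=qol,
            qlq_my20_disease_symptoms=my20_ds,
            qlq_my20_side_effects=my20_se,
            early_mortality=em,
        ))

    cases = _apply_missingness(cases, config, rng)
    cases = _inject_bad_cases(cases, config, rng)

    db = RWEDatabase(cases=cases, db_id=f"synthetic-seed{config.seed}-n{n}")
    return db, ground_truth(config)


def _apply_missingness(cases: list[RWECase], config: GeneratorConfig,
                       rng: np.random.Generator) -> list[RWECase]:
    from dataclasses import replace
    rates = {f: r for f, r in sorted(config.missingness.items()) if r > 0}
    if not rates:
        return cases
    out = []
    for case in cases:
        overrides = {f: None for f, r in rates.items() if rng.random() < r}
        out.append(replace(case, **overrides) if overrides else case)
    return out


def _inject_bad_cases(cases: list[RWECase], config: GeneratorConfig,
                      rng: np.random.Generator) -> list[RWECase]:
    from dataclasses import replace
    total = config.n_off_cpg + config.n_incomplete
    if total == 0:
        return cases
    picked = rng.choice(len(cases), size=total, replace=False)
    off_cpg = set(picked[:config.n_off_cpg].tolist())
    incomplete = set(picked[config.n_off_cpg:].tolist())
    out = []
    for i, case in enumerate(cases):
        if i in off_cpg:
            # an outdated strategy absent from the current guideline set
            out.append(replace(case, regimen_id=config.off_cpg_regimen_id,
                               remission_post_asct=None, early_mortality=None,
                               maintenance_substance=None))
        elif i in incomplete:
            out.append(replace(case, ttnt_days=None))
        else:
            out.append(case)
    return out


# ---------------------------------------------------------------------------
# Curation (guideline filter + outcome completeness)
# ---------------------------------------------------------------------------

def required_outcome_fields(case: RWECase, regimens: dict[str, Regimen]) -> tuple[str, ...]:
    base = ("remission_post_induction", "ttnt_days", "ae_grade3plus", "qlq_c30_global")
    regimen = regimens.get(case.regimen_id)
    if regimen is not None and regimen.includes_asct:
        return base + ("remission_post_asct", "early_mortality")
    return base


def curate(db: RWEDatabase, regimens: dict[str, Regimen]) -> tuple[RWEDatabase, list[dict]]:
    """Apply the two curation filters and log each removal with its rule.

    Removes (1) cases on regimens outside the guideline-compliant registry
    and (2) cases missing a required endpoint.  Idempotent.
    """
    compliant = {rid for rid, r in regimens.items() if r.cpg_status == "cpg_compliant"}
    kept: list[RWECase] = []
    log: list[dict] = []
    for case in db.cases:
        if case.regimen_id not in compliant:
            log.append({"case_id": case.case_id, "rule": "off_cpg_regimen",
                        "detail": case.regimen_id})
            continue
        missing = [f for f in required_outcome_fields(case, regimens)
                   if getattr(case, f) is None]
        if missing:
            log.append({"case_id": case.case_id, "rule": "incomplete_outcome",
                        "detail": ",".join(missing)})
            continue
        kept.append(case)
    return RWEDatabase(cases=kept, db_id=db.db_id + "-curated"), log


def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
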