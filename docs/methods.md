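# Methods

## Scope and model

`mmdt` implements a similarity-based digital twin for first-line multiple
myeloma (MM) treatment decision support.  It is not a predictive statistical
model: it is a deterministic clinical-inference engine coupled to an empirical
outcome summarizer.  Four layers:

1. **Entity description** — every clinical parameter is a typed *entity*
   ("observed" when directly documentable, "calculated" when derived by a
   rule), with a declared value domain (kind, canonical unit, range or
   categories) and representative LOINC/SNOMED-CT bindings as metadata.
   Entity ids are lower-snake internal strings; terminology codes are never
   keys, so everything is resolvable offline.
2. **Entity network** — entities as nodes, causal edges restricted to four
   predicates (`derives`, `influences`, `contains`, `treats`), serialized to
   TURTLE under a custom namespace.  The `derives` subgraph is required to be
   a DAG.  The shipped reference network has 74 entities and 81 edges: every
   entity the worked example, the operator pack, the five endpoints, the
   regimen registry and the warning rules touch.  It is deliberately a
   reduced instance; completeness of MM knowledge is not claimed.
3. **Formal logic** — one operator per calculated entity.  Evaluation is
   recursive with memoization: calculated inputs trigger their own operator
   first, each operator executes at most once per instantiation, and every
   execution is recorded in an append-only trace (operator id, consumed
   inputs with values and origins, produced value, execution index).  The
   trace powers the Sankey provenance export and the trace summary
   (distinct observed factors, distinct operators).
4. **Real-world evidence** — per-endpoint twin cohorts are exact-match
   filters over derived categorical measures, and endpoint results are the
   cohorts' empirical distributions.  No distances, propensity scores,
   survival models or rankings.

## Missing-data semantics

All rule outputs that assert a clinical state use Kleene three-valued logic:
*yes* dominates disjunctions, *no* requires complete negative data, anything
else is *unknown*.  Consequences:

- High-risk cytogenetics: one positive marker of {t(4;14), t(14;16),
  del(17p), gain(1q21), t(14;20)} suffices for *yes*; *no* requires all five
  documented negative; four negatives plus one missing stays *unknown*.
- A value documented directly for a calculated entity (e.g. a recorded
  Charlson index) short-circuits derivation and counts as an observed factor
  in the trace.
- Warning rules fire only on *yes* triggers: a missing lab emits no warning.
- Cases in the RWE database whose constrained measure is unknown are
  excluded from cohorts; missingness never matches.

Two deliberate refinements of naive Kleene-OR, both in the spirit of
"conclude exactly what partial data decides":

- ISS staging: β2-microglobulin ≥ 5.5 mg/L → stage III without albumin, and
  β2M in [3.5, 5.5) → stage II without albumin (stage I is already
  impossible); only β2M < 3.5 with missing albumin is undecidable.
- Renal insufficiency: creatinine is the primary criterion (eGFR is
  creatinine-derived), so a documented normal creatinine yields *no* even
  with eGFR missing; *unknown* only when both are absent.

## The operator pack

Thresholds ship in `src/mmdt/data/thresholds.json` and are overridable.

- **CRAB**: anemia (Hb < 10 g/dl or < LLN−2), hypercalcemia (Ca > 2.75
  mmol/L or > ULN+0.25), renal insufficiency (creatinine > 2.0 mg/dl or
  eGFR < 40 ml/min), bone lesions (count ≥ 1); CRAB is the tri-state OR.
- **SLiM**: clonal plasma cells ≥ 60 %, involved/uninvolved FLC ratio ≥ 100,
  > 1 focal MRI lesion.
- **CCI**: unadjusted Charlson weight sum over 17 condition flags (standard
  weight table in `charlson_weights.json`); age enters fitness separately to
  avoid double counting.
- **Karnofsky→ECOG**: 90–100→0, 70–80→1, 50–60→2, 30–40→3, 10–20→4 (<10→5).
  ECOG is preferred when both are documented.
- **Fitness** (the one measure with no published closed form): a points
  concretization inspired by geriatric-assessment practice — age ≤65/66–75/>75
  → 0/1/2, ECOG ≤1/2/≥3 → 0/1/2, CCI ≤1/2–3/≥4 → 0/1/2; total ≤1 *fit*,
  2–3 *intermediate*, ≥4 *frail*.  With a missing component the class is
  reported only when optimistic and pessimistic completions agree (verified
  against brute-force enumeration in the tests).  The rule reproduces the
  reference example (age 55, ECOG 0, CCI 2 → fit) and is config-swappable.

## Endpoints and cohorts

Five endpoints, each with its own similarity profile
(`similarity_profiles.yaml`): remission (IMWG categories sCR…PD, reported
separately post-induction and post-ASCT for transplant strategies), time to
next treatment (TTNT, arithmetic mean of recorded days; unrecorded next
treatments are excluded from the mean and counted — a completeness bias noted
here deliberately), adverse events (grade ≥3 proportion), quality of life
(cohort QLQ-C30 global-health tertiles around the cohort median; QLQ-MY20
scales are carried as raw fields), and early mortality (death ≤ 100 days
after ASCT, boundary inclusive, computed only for ASCT strategies; a
`death_days_after_asct` column is classified with that window on load).
Remission/TTNT/EM cohorts constrain all three measures; QOL/AE constrain
fitness only.  Minimum cohort size defaults to 10 with a low-evidence flag —
no automatic constraint relaxation, so evidence quality is never hidden.

Eligibility is encoded per regimen: transplant strategies require *fit*;
the non-transplant backbones are reserved for non-fit patients.
Refractoriness to a contained substance is a hard conflict.  Guideline
status is static regimen metadata.  Reports list options in id order and
contain no rank, score or "best" field.

## Synthetic RWE generator

The generator emulates a *curated*, analysis-ready first-line cohort.
Covariates: age ~ N(68, 9) truncated [35, 90]; ECOG ~ multinomial
(.35, .35, .20, .08, .02); CCI ~ Poisson(1.2); marker prevalences
.12/.03/.10/.30/.02; albumin ~ N(3.7, 0.6) g/dl; β2M ~ LogNormal(ln 3.5,
0.5) mg/L.  Assignment: fit → VRD+ASCT .6 / VCD+ASCT .4; non-fit → VRD .7 /
VCD .3; maintenance uniform over {bortezomib, lenalidomide, ixazomib}.

Outcomes are generated conditionally on exactly the three matched measures:
remission by ordered logit on a latent scale (regimen effect VRD > VCD,
post-ASCT deepening, high-risk and ISS penalties), TTNT lognormal with
multiplicative shifts, AE and EM Bernoulli, QOL truncated normal.  The
response conditionals are deliberately low-entropy (one dominant category)
— synthetic magnitudes chosen for test power, not clinical estimates.  A
sidecar records every conditional actually used, enabling the recovery tests
(matched remission distribution within ±3 pp per category; EM and TTNT
within 3 standard errors at n = 5 000, seed 2025, cohort ≈ 400).

What the generator does *not* emulate: longitudinal multi-line trajectories,
correlated repeated measurements, informative missingness, site effects, and
real covariate–outcome structure.  Passing recovery tests therefore shows
the engine is correct *when matching is correctly specified*, not that exact
matching suffices on real registry data; the
`unmatched_covariate_effect` switch demonstrates the residual-confounding
failure mode (a latent outcome driver flattens the matched distribution
beyond the recovery band).

Missingness defaults to 0 per field (opt-in rates serve the missing-data
tests).  Curation-filter injections are integer counts (`n_off_cpg`,
`n_incomplete`) rather than rates so removal bookkeeping is deterministic.
Identical config ⇒ byte-identical CSV.

## Numerical and engineering choices

- Unit normalization happens at profile load against each entity's canonical
  unit (g/l↔g/dl, µmol/L→mg/dl creatinine, mg/dl→mmol/L calcium, …);
  repeated measurements reduce to latest-at-or-before the decision date,
  undated records being overridden by any dated one.
- Headline states break proportion ties by the declared category order
  (sCR…PD for remission), making reports deterministic.
- Distribution denominators exclude members missing the outcome; the
  excluded count is always reported alongside.
- The recursive engine is validated against an independent non-recursive
  topological evaluator on randomized operator DAGs (100 DAGs, seeded), and
  cyclic registries are rejected before evaluation.
- TURTLE round-trips are checked structurally (ids, types, domains, edges);
  multi-valued RDF properties are unordered, so category/binding order is
  not structural content.
- Problem sizes used by the test suite: n = 5 000 cases for the shared study
  database, 1 000 for matching oracles, 10 000 for one prevalence
  calibration; the full suite runs in a few seconds.

## Known limitations

- The reference knowledge base is a reduced instance; counts of entities,
  edges and operators are properties of this instance, not of MM knowledge.
- QOL aggregation of the myeloma-specific questionnaire subscales is not
  defined; only the QLQ-C30 global score is summarized.
- TTNT excludes censored cases from the mean, which biases it upward toward
  patients who progressed; survival-analysis endpoints are out of scope.
- FHIR alignment is a shaped-JSON export, not profile conformance.
- Conflicts beyond refractoriness and eligibility (e.g. drug–drug
  interactions) are expressible through the rule interface but not shipped.
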