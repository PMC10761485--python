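"""The myeloma rule pack: staging, criteria, fitness, proxies, tri-state laws."""

import itertools

import pytest

from mmdt import scores
from mmdt.characterize import derive_similarity_features
from mmdt.engine import EvaluationContext, trace_summary
from mmdt.scores import DomainError
from mmdt.tristate import NO, UNKNOWN, YES, TriState, tri_or
from mmdt.values import ClinicalValue

TRI = (YES, NO, UNKNOWN)


class TestIssStage:
    @pytest.mark.parametrize("albumin,b2m,expected", [
        (3.1, 3.3, 2),       # the worked-example patient
        (3.5, 3.49, 1),      # boundary: both criteria just satisfied
        (3.49, 3.49, 2),     # albumin below the stage-I cutoff
        (3.5, 3.5, 2),       # b2m at the stage-I cutoff
        (4.0, 5.5, 3),       # b2m at the stage-III cutoff
        (None, 6.0, 3),      # stage III decidable without albumin
        (None, 3.0, None),   # stage I vs II undecidable without albumin
        (None, 4.0, 2),      # b2m alone forces stage II
        (3.8, None, None),   # no b2m, no stage
    ])
    def test_staging_rule(self, albumin, b2m, expected):
        assert scores.iss_stage(albumin, b2m) == expected

    def test_negative_input_rejected(self):
        with pytest.raises(DomainError):
            scores.iss_stage(-1.0, 3.0)

    def test_monotone_in_b2m_at_fixed_albumin(self):
        for albumin in (2.5, 3.5, 4.5):
            stages = [scores.iss_stage(albumin, b2m / 10) for b2m in range(1, 120)]
            assert stages == sorted(stages)


class TestCrabComponents:
    @pytest.mark.parametrize("fn,value,expected", [
        (scores.anemia, 9.5, YES),
        (scores.anemia, 13.0, NO),
        (scores.anemia, None, UNKNOWN),
        (scores.hypercalcemia, 2.9, YES),
        (scores.hypercalcemia, 2.4, NO),
        (scores.hypercalcemia, None, UNKNOWN),
        (scores.bone_lesions, 1, YES),
        (scores.bone_lesions, 0, NO),
        (scores.bone_lesions, None, UNKNOWN),
    ])
    def test_single_input_components(self, fn, value, expected):
        assert fn(value) is expected

    def test_anemia_relative_to_lower_limit(self):
        assert scores.anemia(10.5, lln=13.0) is YES   # > absolute cutoff but 2 below LLN
        assert scores.anemia(11.5, lln=13.0) is NO

    @pytest.mark.parametrize("creatinine,egfr,expected", [
        (2.4, None, YES),
        (None, 35.0, YES),   # either criterion suffices
        (1.0, None, NO),     # creatinine primary: decided without eGFR
        (1.0, 35.0, YES),
        (None, None, UNKNOWN),
    ])
    def test_renal_insufficiency(self, creatinine, egfr, expected):
        assert scores.renal_insufficiency(creatinine, egfr) is expected

    @pytest.mark.parametrize("states,expected", [
        ((NO, NO, YES, NO), YES),
        ((NO, NO, NO, UNKNOWN), UNKNOWN),  # absence needs complete data
        ((NO, NO, NO, NO), NO),
        ((UNKNOWN, UNKNOWN, YES, UNKNOWN), YES),
    ])
    def test_crab_disjunction(self, states, expected):
        assert scores.crab(*states) is expected

    @pytest.mark.parametrize("pc,flc,mri,expected", [
        (60.0, None, None, YES),
        (59.9, 100.0, None, YES),
        (10.0, 5.0, 1, NO),      # MRI lesions must exceed one
        (10.0, 5.0, 2, YES),
        (10.0, None, 0, UNKNOWN),
    ])
    def test_slim_biomarkers(self, pc, flc, mri, expected):
        assert scores.slim(pc, flc, mri) is expected


class TestHighRiskCytogenetics:
    def test_all_five_documented_negative(self):
        assert scores.high_risk_cytogenetics(NO, NO, NO, NO, NO) is NO

    def test_one_positive_suffices_despite_missing_rest(self):
        assert scores.high_risk_cytogenetics(UNKNOWN, UNKNOWN, YES, UNKNOWN, UNKNOWN) is YES

    def test_four_negative_one_missing_stays_unknown(self):
        assert scores.high_risk_cytogenetics(NO, NO, NO, NO, UNKNOWN) is UNKNOWN


class TestTriStateLaws:
    @pytest.mark.parametrize("arity", [2, 3, 4, 5])
    def test_disjunction_commutative_over_all_tuples(self, arity):
        for tup in itertools.product(TRI, repeat=arity):
            value = tri_or(tup)
            for perm in itertools.permutations(tup):
                assert tri_or(perm) is value

    @pytest.mark.parametrize("arity", [2, 3, 4, 5])
    def test_information_monotonicity_exhaustive(self, arity):
        """Filling in an unknown never flips an already-determined output."""
        for tup in itertools.product(TRI, repeat=arity):
            before = tri_or(tup)
            for i, v in enumerate(tup):
                if v is not UNKNOWN:
                    continue
                for concrete in (YES, NO):
                    after = tri_or(tup[:i] + (concrete,) + tup[i + 1:])
                    if before is not UNKNOWN:
                        assert after is before
                    else:
                        assert after in TRI


class TestComorbidityAndPerformance:
    def test_charlson_sum(self):
        assert scores.cci_score([]) == 0
        assert scores.cci_score(["diabetes_without_complication", "renal_disease"]) == 3
        assert scores.cci_score(["metastatic_solid_tumor", "aids"]) == 12
        assert scores.cci_score(None) is None

    def test_unknown_condition_rejected(self):
        with pytest.raises(DomainError):
            scores.cci_score(["bad_hair_day"])

    @pytest.mark.parametrize("kps,expected", [
        (100, 0), (90, 0), (80, 1), (70, 1), (60, 2), (50, 2),
        (40, 3), (30, 3), (20, 4), (10, 4), (5, 5), (None, None),
    ])
    def test_karnofsky_to_ecog(self, kps, expected):
        assert scores.ecog_from_karnofsky(kps) == expected

    def test_karnofsky_outside_range_rejected(self):
        with pytest.raises(DomainError):
            scores.ecog_from_karnofsky(110)


class TestFitness:
    @pytest.mark.parametrize("age,ecog,kps,cci,expected", [
        (55, 0, None, 2, "fit"),        # the worked-example patient
        (80, 3, None, 5, "frail"),      # maximal points
        (55, None, 100, 1, "fit"),      # Karnofsky proxy in place of ECOG
        (70, 1, None, 0, "fit"),
        (70, 2, None, 2, "intermediate"),
        (None, 0, None, 0, None),       # age is mandatory
        (55, None, None, None, None),   # bounds straddle classes
    ])
    def test_classification(self, age, ecog, kps, cci, expected):
        assert scores.fitness(age, ecog, kps, cci) == expected

    def test_karnofsky_proxy_with_missing_cci_bounds_agree(self):
        # age 55 (0 pts) + KPS 100 -> ECOG 0 (0 pts); a missing CCI spans
        # 0..2 points, straddling fit/intermediate -> undetermined, exactly
        # as the brute-force enumeration over completions concludes
        assert scores.fitness(55, None, 100.0, None) is None
        assert scores.fitness_bruteforce(55, None, 100.0, None) is None

    def test_bounds_logic_matches_bruteforce_enumeration(self):
        ages = [40, 55, 66, 70, 76, 88]
        ecogs = [None, 0, 1, 2, 3, 4]
        ccis = [None, 0, 1, 2, 3, 4, 7]
        for age, ecog, cci in itertools.product(ages, ecogs, ccis):
            assert scores.fitness(age, ecog, None, cci) == \
                scores.fitness_bruteforce(age, ecog, None, cci), (age, ecog, cci)


class TestOperatorInputDeclarations:
    class _Instrumented(dict):
        def __init__(self, *args):
            super().__init__(*args)
            self.accessed = set()

        def __getitem__(self, key):
            self.accessed.add(key)
            return super().__getitem__(key)

    @staticmethod
    def _present_value(network, entity_id):
        domain = network.entities[entity_id].value_domain
        if domain.kind == "numeric":
            lo, hi = domain.range or (0.0, 1.0)
            return ClinicalValue.number((lo + hi) / 2, domain.unit)
        if domain.kind == "boolean":
            return ClinicalValue.tristate(YES)
        return ClinicalValue.category(domain.categories[0])

    def test_rules_read_exactly_their_declared_inputs(self, ref_kb):
        for spec in ref_kb.registry.specs():
            accessed_union = set()
            for configuration in ("unknown", "present"):
                inputs = self._Instrumented({
                    eid: (ClinicalValue.unknown() if configuration == "unknown"
                          else self._present_value(ref_kb.network, eid))
                    for eid in spec.input_entities})
                spec.rule(inputs)
                assert inputs.accessed <= set(spec.input_entities), spec.id
                accessed_union |= inputs.accessed
            assert accessed_union == set(spec.input_entities), spec.id


class TestDeriveSimilarityFeatures:
    def test_worked_example_patient(self, ref_kb, table2_profile):
        features, trace = derive_similarity_features(
            table2_profile.observations, ref_kb.registry, ref_kb.network)
        assert features.fitness == "fit"
        assert features.high_risk_cytogenetics is NO
        assert features.iss_stage == 2
        assert trace_summary(trace) == (10, 3)

    def test_empty_profile_yields_all_unknown(self, ref_kb):
        features, trace = derive_similarity_features({}, ref_kb.registry, ref_kb.network)
        assert features.fitness is None
        assert features.high_risk_cytogenetics is UNKNOWN
        assert features.iss_stage is None
        # the Charlson operator additionally fires trying to derive the
        # undocumented comorbidity index, hence 4 executed operators
        assert trace_summary(trace) == (0, 4)

    def test_partial_profile_by_hand(self, ref_kb):
        observations = {
            "del_17p": ClinicalValue.tristate(YES),
            "age": ClinicalValue.number(70, "years"),
            "ecog": ClinicalValue.number(1, "dimensionless"),
            "cci": ClinicalValue.number(0, "dimensionless"),
        }
        features, _ = derive_similarity_features(observations, ref_kb.registry, ref_kb.network)
        assert features.fitness == "fit"           # 1 + 0 + 0 points
        assert features.high_risk_cytogenetics is YES
        assert features.iss_stage is None


class TestEarlyMortalityWindow:
    @pytest.mark.parametrize("days,expected", [
        (50, YES), (100, YES), (101, NO), (365, NO), (None, NO),
    ])
    def test_hundred_day_window_boundary(self, days, expected):
        assert scores.early_mortality_from_days(days) is expected
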