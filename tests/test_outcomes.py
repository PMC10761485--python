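"""Outcome assembly: options, distributions, TTNT, warnings, full reports."""

import json
import math

import numpy as np
import pytest

import mmdt
from mmdt.matching import RWECase, RWEDatabase, TwinCohort
from mmdt.outcomes import (AssessmentReport, candidate_options, endpoint_distribution,
                           infer_warnings, qol_summary, ttnt_mean)
from mmdt.patient import PatientProfile
from mmdt.scores import SimilarityFeatures
from mmdt.tristate import NO
from mmdt.values import ClinicalValue

FIT_NO_2 = SimilarityFeatures("fit", NO, 2)
FRAIL_NO_2 = SimilarityFeatures("frail", NO, 2)


def _profile(**kwargs):
    defaults = dict(patient_id="p1", therapy_line=1)
    defaults.update(kwargs)
    return PatientProfile(**defaults)


def _cohort(case_ids, endpoint="remission"):
    return TwinCohort(endpoint=endpoint, case_ids=tuple(sorted(case_ids)),
                      matched_on={}, regimen_id="VRD_ASCT", therapy_line=1,
                      low_evidence=len(case_ids) < 10)


def _case(cid, **kwargs):
    return RWECase(case_id=cid, regimen_id="VRD_ASCT", **kwargs)


class TestCandidateOptions:
    def test_fit_patient_gets_both_transplant_strategies(self, regimens):
        options, conflicts = candidate_options(FIT_NO_2, _profile(), regimens)
        assert [o.id for o in options] == ["VCD_ASCT", "VRD_ASCT"]
        assert all(set(o.maintenance_options) == {"bortezomib", "lenalidomide", "ixazomib"}
                   for o in options)
        assert {c.regimen_id for c in conflicts} == {"VRD", "VCD"}

    def test_refractory_substance_excludes_containing_regimen(self, regimens):
        options, conflicts = candidate_options(
            FIT_NO_2, _profile(refractory_substances=("lenalidomide",)), regimens)
        assert [o.id for o in options] == ["VCD_ASCT"]
        reasons = {c.regimen_id: c.reason for c in conflicts}
        assert reasons["VRD_ASCT"] == "refractory: lenalidomide"

    def test_frail_patient_gets_no_transplant_options(self, regimens):
        options, _ = candidate_options(FRAIL_NO_2, _profile(), regimens)
        assert [o.id for o in options] == ["VCD", "VRD"]
        assert not any(o.includes_asct for o in options)

    def test_unknown_fitness_is_conservative(self, regimens):
        options, conflicts = candidate_options(
            SimilarityFeatures(None, NO, 2), _profile(), regimens)
        assert options == []
        assert all("undetermined" in c.reason for c in conflicts)


class TestEndpointDistribution:
    def test_counting_example(self):
        cases = [_case("a", remission_post_induction="CR"),
                 _case("b", remission_post_induction="CR"),
                 _case("c", remission_post_induction="VGPR"),
                 _case("d", remission_post_induction="PD")]
        db = RWEDatabase(cases=cases)
        result = endpoint_distribution(_cohort([c.case_id for c in cases]), db,
                                       "remission", "post_induction")
        assert result.distribution == {"CR": 0.5, "VGPR": 0.25, "PD": 0.25}
        assert result.headline_state == "CR"
        assert result.n_contributing == 4 and result.n_missing_outcome == 0

    def test_whole_database_equals_empirical_frequencies(self, synthetic_world):
        db = synthetic_world["curated"]
        ids = [c.case_id for c in db.cases if c.regimen_id == "VRD_ASCT"]
        result = endpoint_distribution(_cohort(ids), db, "remission", "post_induction")
        counts = {}
        for c in db.cases:
            if c.regimen_id == "VRD_ASCT":
                counts[c.remission_post_induction] = counts.get(c.remission_post_induction, 0) + 1
        for state, count in counts.items():
            assert result.distribution[state] == pytest.approx(count / len(ids))

    def test_distribution_normalizes_and_denominators_account(self, synthetic_world):
        db = synthetic_world["curated"]
        ids = [c.case_id for c in db.cases[:500] if c.regimen_id.endswith("_ASCT")]
        for endpoint, stage in (("remission", "post_induction"), ("remission", "post_asct"),
                                ("ae", None), ("em", None)):
            result = endpoint_distribution(_cohort(ids), db, endpoint, stage)
            assert abs(sum(result.distribution.values()) - 1.0) < 1e-9
            assert all(p >= 0 for p in result.distribution.values())
            assert result.n_contributing + result.n_missing_outcome == result.cohort_size

    def test_members_missing_the_outcome_excluded_from_denominator(self):
        cases = [_case("a", remission_post_induction="CR"),
                 _case("b", remission_post_induction=None)]
        db = RWEDatabase(cases=cases)
        result = endpoint_distribution(_cohort(["a", "b"]), db, "remission", "post_induction")
        assert result.distribution == {"CR": 1.0}
        assert result.n_missing_outcome == 1

    def test_empty_cohort_flagged_no_evidence(self):
        result = endpoint_distribution(_cohort([]), RWEDatabase(cases=[]), "em")
        assert result.distribution == {} and "no_evidence" in result.flags


class TestTtnt:
    def test_mean_of_two(self):
        db = RWEDatabase(cases=[_case("a", ttnt_days=300.0), _case("b", ttnt_days=500.0)])
        assert ttnt_mean(_cohort(["a", "b"]), db).mean_days == 400.0

    def test_single_member(self):
        db = RWEDatabase(cases=[_case("a", ttnt_days=123.0)])
        assert ttnt_mean(_cohort(["a"]), db).mean_days == 123.0

    def test_missing_ttnt_excluded_and_counted(self):
        db = RWEDatabase(cases=[_case("a", ttnt_days=300.0), _case("b")])
        result = ttnt_mean(_cohort(["a", "b"]), db)
        assert result.mean_days == 300.0
        assert result.n_missing_outcome == 1

    def test_no_recorded_ttnt_is_no_evidence(self):
        db = RWEDatabase(cases=[_case("a")])
        assert "no_evidence" in ttnt_mean(_cohort(["a"]), db).flags

    def test_lognormal_sample_mean_within_three_standard_errors(self):
        rng = np.random.default_rng(4242)
        meanlog, sdlog, n = math.log(600.0), 0.5, 1000
        draws = rng.lognormal(meanlog, sdlog, n)
        db = RWEDatabase(cases=[_case(f"c{i:04d}", ttnt_days=float(d))
                                for i, d in enumerate(draws)])
        result = ttnt_mean(_cohort([c.case_id for c in db.cases]), db)
        true_mean = math.exp(meanlog + sdlog ** 2 / 2)
        true_sd = true_mean * math.sqrt(math.exp(sdlog ** 2) - 1)
        assert abs(result.mean_days - true_mean) < 3 * true_sd / math.sqrt(n)


class TestQol:
    def test_tertile_summary(self):
        scores_ = [20.0, 40.0, 50.0, 60.0, 70.0, 90.0]
        db = RWEDatabase(cases=[_case(f"c{i}", qlq_c30_global=s)
                                for i, s in enumerate(scores_)])
        result = qol_summary(_cohort([c.case_id for c in db.cases]), db)
        assert abs(sum(result.distribution.values()) - 1.0) < 1e-9
        assert result.summary["median"] == 55.0
        assert result.headline_state in result.distribution


class TestWarnings:
    def test_elevated_creatinine_triggers_renal_warning(self, regimens):
        profile = _profile(observations={"creatinine": ClinicalValue.number(2.4, "mg/dl")})
        warnings = infer_warnings(profile, regimens["VRD_ASCT"])
        assert len(warnings) == 1 and "lenalidomide" in warnings[0]

    def test_absent_creatinine_triggers_nothing(self, regimens):
        assert infer_warnings(_profile(), regimens["VRD_ASCT"]) == []

    def test_regimen_without_rules(self, regimens):
        profile = _profile(observations={"creatinine": ClinicalValue.number(2.4, "mg/dl")})
        assert infer_warnings(profile, regimens["VCD"]) == []


@pytest.fixture(scope="module")
def report(table2_profile, synthetic_world, profiles, ref_kb, regimens):
    return mmdt.assess(table2_profile, synthetic_world["curated"], profiles,
                       ref_kb, regimens, seed=1)


class TestAssessment:
    def test_both_transplant_strategies_with_five_endpoints(self, report):
        assert [o.regimen_id for o in report.options] == ["VCD_ASCT", "VRD_ASCT"]
        for option in report.options:
            endpoints = {r.endpoint for r in option.endpoint_results}
            assert endpoints == {"remission", "ttnt", "qol", "ae", "em"}
            assert option.cpg_label == "cpg_compliant"
            remission_stages = [r.stage for r in option.endpoint_results
                                if r.endpoint == "remission"]
            assert remission_stages == ["post_induction", "post_asct"]

    def test_report_has_no_best_option_designation(self, report):
        payload = report.to_jsonable()
        assert json.dumps(payload).find('"rank"') == -1
        for option in payload["options"]:
            assert {"rank", "score", "best", "recommended"} & set(option) == set()

    def test_json_round_trip(self, report, tmp_path):
        path = tmp_path / "report.json"
        mmdt.write_report(report, path)
        back = mmdt.read_report(path)
        assert back.to_jsonable() == report.to_jsonable()

    def test_deterministic_given_inputs_and_seed(self, table2_profile, synthetic_world,
                                                 profiles, ref_kb, regimens):
        one = mmdt.assess(table2_profile, synthetic_world["curated"], profiles,
                          ref_kb, regimens, seed=1)
        two = mmdt.assess(table2_profile, synthetic_world["curated"], profiles,
                          ref_kb, regimens, seed=1)
        assert json.dumps(one.to_jsonable(), sort_keys=True) == \
            json.dumps(two.to_jsonable(), sort_keys=True)

    def test_zero_option_report_serializes(self, tmp_path):
        report = AssessmentReport(patient_id="p", therapy_line=1, features=FIT_NO_2,
                                  n_observed_factors=0, n_operators=0, options=[],
                                  conflicts=[], metadata={})
        path = tmp_path / "empty.json"
        mmdt.write_report(report, path)
        assert mmdt.read_report(path).options == []

    def test_schema_version_checked_on_read(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"schema_version": 99}))
        with pytest.raises(ValueError, match="schema version"):
            mmdt.read_report(path)
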