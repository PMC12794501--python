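"""Yield, penalty calibration, precision scoring, safety, and risk."""

import pytest
from hypothesis import given, strategies as st

from ddxeval import (
    Category,
    DiagnosisLabel,
    Group,
    MetricResult,
    PenaltyScheme,
    PenaltyUndefinedError,
    RiskClass,
    RiskFeatureSet,
    RiskLevel,
    SafetyMode,
    Specialty,
    all_raters,
    by_group,
    calibrate_penalty,
    classify_case_risk,
    diagnostic_yield,
    finals_from_cases,
    group_dps,
    inclusion_rate,
    multi_diagnosis_rate,
    safety_backward,
    safety_forward,
    score_assessment,
)
from ddxeval.metrics import CARDIAC_SINGLE, WITHIN_MULTIPLE, NO_DIAGNOSIS
from helpers import counts_cohort, make_assessment, make_rater

REFLEX = DiagnosisLabel.of(Category.REFLEX)
CARDIAC = DiagnosisLabel.of(Category.CARDIAC)
UNEXPLAINED = DiagnosisLabel.of(Category.UNEXPLAINED)
Q25 = PenaltyScheme.fixed(0.25, 5)


class TestMetricResult:
    def test_estimate_must_match_counts(self):
        with pytest.raises(ValueError):
            MetricResult(estimate=50.0, numerator=1, denominator=3)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            MetricResult(estimate=0.0, numerator=0, denominator=0)


class TestPenaltyCalibration:
    @pytest.mark.parametrize("max_len, expected", [(5, 0.25), (3, 0.5), (2, 1.0)])
    def test_reciprocal_of_largest_incorrect_count(self, max_len, expected):
        r = make_rater(0)
        assessments = [
            make_assessment("c0", r, [Category.REFLEX]),
            make_assessment(
                "c1",
                r,
                [Category.REFLEX, Category.CARDIAC, Category.ORTHOSTATIC_HYPOTENSION,
                 Category.PSYCHOGENIC_PSEUDOSYNCOPE, Category.OTHER][:max_len],
            ),
        ]
        scheme = calibrate_penalty(assessments)
        assert scheme.penalty == pytest.approx(expected)
        assert scheme.max_list_len == max_len

    def test_singleton_cohort_is_undefined(self):
        r = make_rater(0)
        assessments = [make_assessment("c0", r, [Category.REFLEX]),
                       make_assessment("c1", r, [])]
        with pytest.raises(PenaltyUndefinedError):
            calibrate_penalty(assessments)

    def test_calibrated_scheme_consistency_enforced(self):
        with pytest.raises(ValueError):
            PenaltyScheme(0.3, 5, source=PenaltyScheme.calibrated(5).source)


class TestScoreAssessment:
    r = make_rater(0)

    def test_hit_with_two_incorrect(self):
        a = make_assessment("c", self.r, [Category.REFLEX, Category.CARDIAC, Category.OTHER])
        assert score_assessment(a, REFLEX, Q25) == pytest.approx(1 - 2 * 0.25)

    def test_abstention_scores_zero(self):
        assert score_assessment(make_assessment("c", self.r, []), REFLEX, Q25) == 0.0

    def test_all_wrong_list_reaches_minus_one(self):
        a = make_assessment(
            "c",
            self.r,
            [Category.REFLEX, Category.ORTHOSTATIC_HYPOTENSION,
             Category.PSYCHOGENIC_PSEUDOSYNCOPE, Category.OTHER],
        )
        assert score_assessment(a, CARDIAC, Q25) == pytest.approx(-1.0)

    def test_unexplained_final_penalizes_everything(self):
        full = make_assessment(
            "c",
            self.r,
            [Category.REFLEX, Category.CARDIAC, Category.ORTHOSTATIC_HYPOTENSION,
             Category.PSYCHOGENIC_PSEUDOSYNCOPE, Category.OTHER],
        )
        assert score_assessment(full, UNEXPLAINED, Q25) == pytest.approx(-1.25)
        assert score_assessment(make_assessment("c", self.r, []), UNEXPLAINED, Q25) == 0.0

    def test_none_final_rejected(self):
        with pytest.raises(ValueError):
            score_assessment(
                make_assessment("c", self.r, [Category.REFLEX]),
                DiagnosisLabel.of(Category.NONE),
                Q25,
            )


class TestYield:
    def test_no_abstentions_is_hundred_percent(self):
        _, assessments = counts_cohort(1, 4, [("hit", 0)] * 4)
        assert diagnostic_yield(assessments, all_raters).estimate == 100.0

    def test_all_abstain_is_zero(self):
        _, assessments = counts_cohort(1, 4, [("abstain", 0)] * 4)
        assert diagnostic_yield(assessments, all_raters).estimate == 0.0

    def test_yield_plus_abstention_is_total(self, reference_cohort):
        _, assessments = reference_cohort
        for g in Group:
            y = diagnostic_yield(assessments, by_group(g))
            abstained = sum(
                a.abstained for a in assessments if a.rater.group is g
            )
            assert y.estimate + 100.0 * abstained / y.denominator == pytest.approx(100.0)

    def test_empty_selection_rejected(self, reference_cohort):
        _, assessments = reference_cohort
        with pytest.raises(ValueError):
            diagnostic_yield(assessments, lambda r: False)


class TestInclusionAndDps:
    def test_single_hit_singleton_is_hundred_percent(self):
        cases, assessments = counts_cohort(1, 1, [("hit", 0)])
        finals = finals_from_cases(cases)
        assert group_dps(assessments, finals, Q25, all_raters).estimate == 100.0
        assert inclusion_rate(assessments, finals, all_raters).estimate == 100.0

    def test_zero_hits_degenerate_ci(self):
        cases, assessments = counts_cohort(1, 10, [("miss", 1)] * 10)
        finals = finals_from_cases(cases)
        res = inclusion_rate(assessments, finals, all_raters)
        assert res.estimate == 0.0
        assert res.ci_low == res.ci_high == 0.0

    def test_dps_never_exceeds_inclusion(self, reference_cohort):
        cases, assessments = reference_cohort
        finals = finals_from_cases(cases)
        scheme = calibrate_penalty(assessments)
        for g in Group:
            dps = group_dps(assessments, finals, scheme, by_group(g))
            inc = inclusion_rate(assessments, finals, by_group(g))
            assert dps.estimate <= inc.estimate

    def test_lost_to_followup_cases_are_excluded(self, reference_cohort):
        cases, assessments = reference_cohort
        finals = finals_from_cases(cases)
        n_lost = sum(not c.followed_up for c in cases)
        res = inclusion_rate(assessments, finals, by_group(Group.AI))
        assert res.denominator == 55 - n_lost

    def test_brute_force_oracle_equivalence(self):
        """group_dps equals a raw re-derivation, hit/miss per assessment."""
        from ddxeval import reference_cohort_config, simulate_cohort
        from dataclasses import replace

        config = replace(reference_cohort_config(11), n_cases=20)
        cases, assessments = simulate_cohort(config)
        finals = finals_from_cases(cases)
        scheme = calibrate_penalty(assessments)
        for g in Group:
            total, n = 0.0, 0
            for a in assessments:
                if a.rater.group is not g or a.case_id not in finals:
                    continue
                n += 1
                listed = [d.canonical for d in a.differential]
                final_cat = finals[a.case_id].canonical
                hit = 1 if final_cat in listed else 0
                total += hit - scheme.penalty * (len(listed) - hit)
            expected = 100.0 * total / n
            assert group_dps(assessments, finals, scheme, by_group(g)).estimate == pytest.approx(expected)

    def test_multi_diagnosis_rate_counts_lists_of_two_or_more(self):
        _, assessments = counts_cohort(1, 4, [("hit", 1), ("hit", 0), ("miss", 2), ("abstain", 0)])
        assert multi_diagnosis_rate(assessments, all_raters).estimate == pytest.approx(50.0)


class TestSafety:
    def _cardiac_cohort(self):
        """Two final-cardiac cases, one reflex case; one rater."""
        from ddxeval import CaseRecord

        cases = [
            CaseRecord("k0", CARDIAC, followed_up=True),
            CaseRecord("k1", CARDIAC, followed_up=True),
            CaseRecord("k2", REFLEX, followed_up=True),
        ]
        r = make_rater(0)
        assessments = [
            make_assessment("k0", r, [Category.CARDIAC]),                      # single cardiac, correct
            make_assessment("k1", r, [Category.REFLEX, Category.CARDIAC]),     # cardiac within multiple
            make_assessment("k2", r, [Category.CARDIAC]),                      # single cardiac, wrong
        ]
        return cases, assessments, r

    def test_forward_single_only_counts_by_final_class(self):
        cases, assessments, _ = self._cardiac_cohort()
        finals = finals_from_cases(cases)
        tab = safety_forward(assessments, finals, all_raters, SafetyMode.SINGLE_ONLY)
        assert tab.total == 2  # the multi-diagnosis call is excluded
        assert tab.counts == {"CARDIAC": 1, "REFLEX": 1}

    def test_forward_first_listed_includes_multi_lists(self):
        cases, assessments, _ = self._cardiac_cohort()
        finals = finals_from_cases(cases)
        tab = safety_forward(assessments, finals, all_raters, SafetyMode.FIRST_LISTED)
        assert tab.total == 2  # k1 leads with reflex, so still 2 cardiac calls
        assert tab.counts == {"CARDIAC": 1, "REFLEX": 1}

    def test_forward_no_calls_gives_empty_table(self):
        cases, assessments = counts_cohort(1, 3, [("hit", 0)] * 3)
        finals = finals_from_cases(cases)
        tab = safety_forward(assessments, finals, all_raters, SafetyMode.SINGLE_ONLY)
        assert tab.total == 0 and tab.counts == {}

    def test_backward_classification(self):
        cases, assessments, _ = self._cardiac_cohort()
        finals = finals_from_cases(cases)
        tab = safety_backward(assessments, finals, all_raters)
        assert tab.total == 2  # one rater x two final-cardiac cases
        assert tab.counts == {CARDIAC_SINGLE: 1, WITHIN_MULTIPLE: 1}
        assert tab.miss_rate() == 0.0

    def test_backward_requires_cardiac_cases(self):
        cases, assessments = counts_cohort(1, 2, [("hit", 0)] * 2)
        finals = finals_from_cases(cases)
        with pytest.raises(ValueError, match="cardiac"):
            safety_backward(assessments, finals, all_raters)

    def test_backward_total_is_raters_times_cardiac_cases(self):
        from ddxeval import CaseRecord

        cases = [CaseRecord("k0", CARDIAC, followed_up=True)]
        raters = [make_rater(i) for i in range(3)]
        assessments = [make_assessment("k0", r, []) for r in raters]
        tab = safety_backward(assessments, finals_from_cases(cases), all_raters)
        assert tab.total == 3
        assert tab.counts == {NO_DIAGNOSIS: 3}
        assert tab.miss_rate() == 100.0


class TestRiskClassification:
    @pytest.mark.parametrize(
        "features, expected",
        [
            (RiskFeatureSet(ecg=RiskLevel.HIGH_MAJOR), RiskClass.HIGH),
            (RiskFeatureSet(event=RiskLevel.HIGH_MINOR), RiskClass.HIGH_MINOR_ONLY),
            (
                RiskFeatureSet(event=RiskLevel.HIGH_MINOR, structural_heart_disease=True),
                RiskClass.HIGH,
            ),
            (RiskFeatureSet(history=RiskLevel.LOW), RiskClass.LOW),
            (RiskFeatureSet(), RiskClass.UNCLASSIFIABLE),
            (
                RiskFeatureSet(event=RiskLevel.LOW, ecg=RiskLevel.HIGH_MAJOR),
                RiskClass.HIGH,
            ),
        ],
    )
    def test_guideline_aggregation(self, features, expected):
        assert classify_case_risk(features) is expected


# ---------------------------------------------------------------------------
# property-based invariants

_CONCRETE = sorted(
    [Category.REFLEX, Category.ORTHOSTATIC_HYPOTENSION, Category.CARDIAC,
     Category.PSYCHOGENIC_PSEUDOSYNCOPE, Category.OTHER],
    key=str,
)


@given(
    st.lists(st.sampled_from(_CONCRETE), unique=True, max_size=5),
    st.sampled_from(_CONCRETE + [Category.UNEXPLAINED]),
)
def test_score_bounds(cats, final_cat):
    """Scores live in [-1, 1] for concrete finals under a calibrated
    penalty, and in [-1.25, 0] when the final is unexplained."""
    a = make_assessment("c", make_rater(0), cats)
    s = score_assessment(a, DiagnosisLabel.of(final_cat), Q25)
    if final_cat is Category.UNEXPLAINED:
        assert -0.25 * 5 <= s <= 0.0
    else:
        assert -1.0 <= s <= 1.0


@given(
    st.lists(st.sampled_from(_CONCRETE), unique=True, max_size=4),
    st.sampled_from(_CONCRETE + [Category.UNEXPLAINED]),
)
def test_appending_an_incorrect_diagnosis_costs_exactly_the_penalty(cats, final_cat):
    candidates = [c for c in _CONCRETE if c not in cats and c is not final_cat]
    if not candidates:
        return
    final = DiagnosisLabel.of(final_cat)
    base = score_assessment(make_assessment("c", make_rater(0), cats), final, Q25)
    extended = score_assessment(
        make_assessment("c", make_rater(0), cats + [candidates[0]]), final, Q25
    )
    assert extended == pytest.approx(base - Q25.penalty)
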