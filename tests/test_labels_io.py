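"""Label canonicalization, table readers/writers, and cohort validation."""

import pytest
from hypothesis import given, strategies as st

from ddxeval import (
    Category,
    DiagnosisLabel,
    Group,
    Specialty,
    RaterInfo,
    SynonymMap,
    UnmappedLabelError,
    canonicalize_label,
    validate_cohort,
)
from ddxeval.io import (
    CohortFormatError,
    read_assessments,
    read_cases,
    read_opinions,
    read_synonyms,
    write_assessments,
    write_cases,
)
from helpers import make_assessment, make_rater


class TestCanonicalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("reflex syncope", Category.REFLEX),
            ("Vasovagal  Syncope", Category.REFLEX),  # case/space normalization
            ("ORTHOSTATIC HYPOTENSION", Category.ORTHOSTATIC_HYPOTENSION),
            ("cardiac", Category.CARDIAC),
            ("pps", Category.PSYCHOGENIC_PSEUDOSYNCOPE),
        ],
    )
    def test_builtin_spellings(self, raw, expected):
        label = canonicalize_label(raw)
        assert label.canonical is expected
        assert label.raw_text == raw  # verbatim preservation

    def test_unknown_string_is_not_guessed(self):
        with pytest.raises(UnmappedLabelError, match="fainting spell"):
            canonicalize_label("fainting spell")

    def test_custom_entry_extends_map(self):
        smap = SynonymMap({"Fainting Spell": Category.REFLEX})
        assert canonicalize_label("fainting  spell", smap).canonical is Category.REFLEX

    def test_empty_text_rejected(self):
        with pytest.raises(ValueError):
            canonicalize_label("   ")

    def test_yaml_round_trip(self, tmp_path):
        smap = SynonymMap({"collapse nos": Category.OTHER})
        p = tmp_path / "synonyms.yaml"
        smap.to_yaml(p)
        assert read_synonyms(p).lookup("Collapse NOS") is Category.OTHER


class TestRaterInvariants:
    def test_ai_requires_specialty_none(self):
        with pytest.raises(ValueError):
            RaterInfo("ai", Group.AI, Specialty.CARDIOLOGY)

    def test_allied_specialty_under_physician_rejected(self):
        with pytest.raises(ValueError):
            RaterInfo("x", Group.PHYSICIAN, Specialty.PARAMEDIC)


ASSESSMENT_CSV = """case_id,rater_id,rater_group,rater_specialty,rank,diagnosis,n_questions,n_tests_suggested,n_interventions_suggested
A,R1,PHYSICIAN,NEUROLOGY,1,reflex syncope,0,2,0
A,R1,PHYSICIAN,NEUROLOGY,2,cardiac,0,2,0
A,R1,PHYSICIAN,NEUROLOGY,3,other,0,2,0
A,R2,ALLIED,PARAMEDIC,0,,1,0,0
"""


class TestReadAssessments:
    def test_rows_assemble_into_ordered_lists(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text(ASSESSMENT_CSV)
        out = read_assessments(p)
        assert len(out) == 2
        a = next(x for x in out if x.rater.rater_id == "R1")
        assert [d.canonical for d in a.differential] == [
            Category.REFLEX,
            Category.CARDIAC,
            Category.OTHER,
        ]
        assert a.n_tests_suggested == 2
        b = next(x for x in out if x.rater.rater_id == "R2")
        assert b.abstained and b.n_questions == 1

    @pytest.mark.parametrize(
        "rows, message",
        [
            ("A,R,PHYSICIAN,NEUROLOGY,1,reflex,0,0,0\nA,R,PHYSICIAN,NEUROLOGY,3,cardiac,0,0,0", "rank gap"),
            ("A,R,PHYSICIAN,NEUROLOGY,1,reflex,0,0,0\nA,R,PHYSICIAN,NEUROLOGY,1,cardiac,0,0,0", "duplicate rank"),
            ("A,R,WIZARD,NEUROLOGY,1,reflex,0,0,0", "unknown group"),
            ("A,R,PHYSICIAN,NEUROLOGY,0,reflex,0,0,0", "abstention row"),
            ("A,R,PHYSICIAN,NEUROLOGY,1,reflex,0,0,0\nA,R,PHYSICIAN,NEUROLOGY,2,vasovagal,0,0,0", "duplicate canonical"),
        ],
    )
    def test_dialect_violations(self, tmp_path, rows, message):
        p = tmp_path / "a.csv"
        header = ASSESSMENT_CSV.splitlines()[0]
        p.write_text(header + "\n" + rows + "\n")
        with pytest.raises(CohortFormatError, match=message):
            read_assessments(p)

    def test_list_longer_than_max_rejected(self, tmp_path):
        header = ASSESSMENT_CSV.splitlines()[0]
        rows = "\n".join(
            f"A,R,PHYSICIAN,NEUROLOGY,{i},{dx},0,0,0"
            for i, dx in enumerate(["reflex", "cardiac", "oh"], start=1)
        )
        p = tmp_path / "a.csv"
        p.write_text(header + "\n" + rows + "\n")
        with pytest.raises(CohortFormatError, match="longer than maximum"):
            read_assessments(p, max_list=2)


class TestRoundTrip:
    def test_write_read_write_is_byte_stable(self, tmp_path):
        r1 = make_rater(1)
        r2 = make_rater(2, Group.AI, Specialty.NONE)
        assessments = [
            make_assessment("A", r1, [Category.REFLEX, Category.CARDIAC], n_tests_suggested=3),
            make_assessment("A", r2, []),
            make_assessment(
                "B",
                r1,
                [Category.ORTHOSTATIC_HYPOTENSION],
                n_questions=2,
            ),
        ]
        p1, p2 = tmp_path / "one.csv", tmp_path / "two.csv"
        write_assessments(assessments, p1)
        again = read_assessments(p1)
        assert again == assessments
        write_assessments(again, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_raw_text_survives_round_trip(self, tmp_path):
        from ddxeval import Assessment

        label = canonicalize_label("Vasovagal  Syncope")
        assessments = [Assessment("A", make_rater(0), (label,))]
        p = tmp_path / "a.csv"
        write_assessments(assessments, p)
        back = read_assessments(p)
        assert back[0].differential[0].raw_text == "Vasovagal  Syncope"

    def test_cases_round_trip_with_risk(self, tmp_path):
        from ddxeval import CaseRecord, RiskFeatureSet, RiskLevel

        cases = [
            CaseRecord(
                "A",
                DiagnosisLabel.of(Category.UNEXPLAINED),
                followed_up=True,
                risk=RiskFeatureSet(event=RiskLevel.HIGH_MINOR, structural_heart_disease=True),
            ),
            CaseRecord("B", None, followed_up=False, risk=RiskFeatureSet()),
        ]
        p1, p2 = tmp_path / "c1.csv", tmp_path / "c2.csv"
        write_cases(cases, p1)
        back = read_cases(p1)
        assert back == cases
        write_cases(back, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_case_with_final_but_no_followup_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("case_id,final_dx,followed_up\nA,reflex,false\n")
        with pytest.raises(CohortFormatError, match="without follow-up"):
            read_cases(p)


class TestValidateCohort:
    def test_complete_cohort_passes(self, reference_cohort):
        cases, assessments = reference_cohort
        report = validate_cohort(assessments, cases)
        assert report.ok
        # 19 raters x 55 cases
        assert report.n_assessments == 19 * 55 == 1045

    def test_missing_pair_reported(self, reference_cohort):
        cases, assessments = reference_cohort
        dropped = assessments[3]
        report = validate_cohort(assessments[:3] + assessments[4:], cases)
        assert not report.ok
        assert (dropped.rater.rater_id, dropped.case_id) in report.missing_pairs

    def test_orphan_assessment_reported(self, reference_cohort):
        cases, assessments = reference_cohort
        orphan = make_assessment("GHOST", make_rater(99), [Category.REFLEX])
        report = validate_cohort(list(assessments) + [orphan], cases)
        assert not report.ok
        assert ("r099", "GHOST") in report.orphan_assessments


class TestOpinionsReader:
    def test_empty_diagnosis_is_abstention(self, tmp_path):
        p = tmp_path / "op.csv"
        p.write_text(
            "case_id,reviewer_id,diagnosis\nA,r1,reflex\nA,r2,reflex\nA,r3,\n"
        )
        ops = read_opinions(p)
        assert [o.abstained for o in ops["A"]] == [False, False, True]


@given(
    st.lists(
        st.sampled_from(sorted(Category.__members__.values(), key=str)[:5]),
        unique=True,
        min_size=0,
        max_size=5,
    )
)
def test_differential_uniqueness_is_enforced(cats):
    """Any duplicate-free category list builds; duplicating any entry fails."""
    cats = [c for c in cats if c not in (Category.NONE, Category.UNEXPLAINED)]
    a = make_assessment("A", make_rater(0), cats)
    assert len(a.differential) == len(cats)
    if cats:
        with pytest.raises(ValueError, match="duplicate"):
            make_assessment("A", make_rater(0), cats + [cats[0]])
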