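"""Builders for hand-constructed cohorts used across the tests."""

from __future__ import annotations

from ddxeval import (
    Assessment,
    CaseRecord,
    Category,
    DiagnosisLabel,
    Group,
    RaterInfo,
    Specialty,
)

#: wrong labels relative to a REFLEX final, in a fixed deterministic order
WRONG_VS_REFLEX = (
    Category.ORTHOSTATIC_HYPOTENSION,
    Category.CARDIAC,
    Category.PSYCHOGENIC_PSEUDOSYNCOPE,
    Category.OTHER,
)


def make_rater(
    i: int = 0,
    group: Group = Group.PHYSICIAN,
    specialty: Specialty = Specialty.GENERAL_PRACTICE,
) -> RaterInfo:
    return RaterInfo(f"r{i:03d}", group, specialty)


def make_assessment(case_id, rater, categories, **kwargs) -> Assessment:
    return Assessment(
        case_id, rater, tuple(DiagnosisLabel.of(c) for c in categories), **kwargs
    )


def counts_cohort(
    n_raters: int,
    n_cases: int,
    plan: list[tuple[str, int]],
    group: Group = Group.PHYSICIAN,
    specialty: Specialty = Specialty.GENERAL_PRACTICE,
    final: Category = Category.REFLEX,
) -> tuple[list[CaseRecord], list[Assessment]]:
    """Cohort whose per-assessment hit/incorrect counts are dictated.

    ``plan`` holds one ``(kind, n_incorrect)`` entry per assessment in
    rater-major order, with kind in {"hit", "miss", "abstain"}.  Every
    case shares the same concrete final diagnosis so that hit lists are
    ``[final] + wrong labels`` and miss lists are wrong labels only.
    """
    assert len(plan) == n_raters * n_cases
    cases = [
        CaseRecord(f"c{j:03d}", DiagnosisLabel.of(final), followed_up=True)
        for j in range(n_cases)
    ]
    wrong = [c for c in WRONG_VS_REFLEX if c is not final]
    assessments = []
    k = 0
    for i in range(n_raters):
        rater = make_rater(i, group, specialty)
        for j in range(n_cases):
            kind, n_inc = plan[k]
            k += 1
            if kind == "abstain":
                cats: list[Category] = []
            elif kind == "hit":
                cats = [final] + wrong[:n_inc]
            elif kind == "miss":
                assert n_inc >= 1
                cats = wrong[:n_inc]
            else:
                raise ValueError(kind)
            assessments.append(make_assessment(f"c{j:03d}", rater, cats))
    return cases, assessments
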