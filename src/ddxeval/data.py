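"""Domain records: raters, assessments, cases, and cohort validation.

One *assessment* is one rater's ordered differential-diagnosis list for
one referral letter (case).  An abstention — the rater established no
diagnosis — is an empty differential, never a list containing ``NONE``.
A *case record* carries the committee-adjudicated final diagnosis, which
exists only for cases that completed follow-up.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .labels import Category, DIFFERENTIAL_CATEGORIES, FINAL_CATEGORIES, DiagnosisLabel

__all__ = [
    "Group",
    "Specialty",
    "RaterInfo",
    "Assessment",
    "CaseRecord",
    "RiskLevel",
    "RiskFeatureSet",
    "ValidationReport",
    "validate_cohort",
    "finals_from_cases",
    "by_group",
    "by_specialty",
    "all_raters",
]


class Group(str, enum.Enum):
    PHYSICIAN = "PHYSICIAN"
    ALLIED = "ALLIED"
    AI = "AI"

    def __str__(self) -> str:
        return self.value


class Specialty(str, enum.Enum):
    NEUROLOGY = "NEUROLOGY"
    CARDIOLOGY = "CARDIOLOGY"
    GERIATRICS = "GERIATRICS"
    INTERNAL_MEDICINE = "INTERNAL_MEDICINE"
    GENERAL_PRACTICE = "GENERAL_PRACTICE"
    NURSE_PRACTITIONER = "NURSE_PRACTITIONER"
    PHYSICIAN_ASSISTANT = "PHYSICIAN_ASSISTANT"
    PARAMEDIC = "PARAMEDIC"
    NONE = "NONE"

    def __str__(self) -> str:
        return self.value


PHYSICIAN_SPECIALTIES = frozenset(
    {
        Specialty.NEUROLOGY,
        Specialty.CARDIOLOGY,
        Specialty.GERIATRICS,
        Specialty.INTERNAL_MEDICINE,
        Specialty.GENERAL_PRACTICE,
    }
)
ALLIED_SPECIALTIES = frozenset(
    {
        Specialty.NURSE_PRACTITIONER,
        Specialty.PHYSICIAN_ASSISTANT,
        Specialty.PARAMEDIC,
    }
)


@dataclass(frozen=True)
class RaterInfo:
    """Identity and affiliation of one diagnostician."""

    rater_id: str
    group: Group
    specialty: Specialty

    def __post_init__(self) -> None:
        if self.group is Group.AI and self.specialty is not Specialty.NONE:
            raise ValueError(f"AI rater {self.rater_id!r} must have specialty NONE")
        if self.group is Group.PHYSICIAN and self.specialty not in PHYSICIAN_SPECIALTIES:
            raise ValueError(
                f"rater {self.rater_id!r}: specialty {self.specialty} is not a physician specialty"
            )
        if self.group is Group.ALLIED and self.specialty not in ALLIED_SPECIALTIES:
            raise ValueError(
                f"rater {self.rater_id!r}: specialty {self.specialty} is not an allied specialty"
            )


@dataclass(frozen=True)
class Assessment:
    """One rater's ordered differential for one case.

    ``differential[0]`` is the first-proposed (rank-1) diagnosis.  The
    pass-through counts record how many clarifying questions, additional
    tests and therapeutic interventions the rater suggested; they are
    carried, not scored.
    """

    case_id: str
    rater: RaterInfo
    differential: tuple[DiagnosisLabel, ...] = ()
    n_questions: int = 0
    n_tests_suggested: int = 0
    n_interventions_suggested: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "differential", tuple(self.differential))
        cats = [d.canonical for d in self.differential]
        for c in cats:
            if c not in DIFFERENTIAL_CATEGORIES:
                raise ValueError(
                    f"category {c} may not appear inside a differential "
                    f"(case {self.case_id}, rater {self.rater.rater_id})"
                )
        if len(set(cats)) != len(cats):
            raise ValueError(
                f"duplicate canonical categories in differential "
                f"(case {self.case_id}, rater {self.rater.rater_id})"
            )
        for name in ("n_questions", "n_tests_suggested", "n_interventions_suggested"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def abstained(self) -> bool:
        return len(self.differential) == 0

    @property
    def categories(self) -> frozenset[Category]:
        return frozenset(d.canonical for d in self.differential)


class RiskLevel(str, enum.Enum):
    """Per-domain risk grading of a referral letter's documentation."""

    NOT_MENTIONED = "NOT_MENTIONED"
    LOW = "LOW"
    HIGH_MINOR = "HIGH_MINOR"
    HIGH_MAJOR = "HIGH_MAJOR"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class RiskFeatureSet:
    """Guideline risk features across the four assessment domains.

    Domains follow the structured syncope work-up: the syncopal event
    itself, past medical history, physical examination, and ECG.
    ``structural_heart_disease`` modifies how high-minor features are
    aggregated.
    """

    event: RiskLevel = RiskLevel.NOT_MENTIONED
    history: RiskLevel = RiskLevel.NOT_MENTIONED
    exam: RiskLevel = RiskLevel.NOT_MENTIONED
    ecg: RiskLevel = RiskLevel.NOT_MENTIONED
    structural_heart_disease: bool = False

    @property
    def domains(self) -> tuple[RiskLevel, RiskLevel, RiskLevel, RiskLevel]:
        return (self.event, self.history, self.exam, self.ecg)


@dataclass(frozen=True)
class CaseRecord:
    """A case's adjudicated final diagnosis and follow-up status.

    ``final_dx`` is defined only when the case completed follow-up; a
    case lost to follow-up keeps its Phase-1 assessments but has no
    reference diagnosis.
    """

    case_id: str
    final_dx: DiagnosisLabel | None
    followed_up: bool = True
    risk: RiskFeatureSet | None = None

    def __post_init__(self) -> None:
        if self.followed_up:
            if self.final_dx is None:
                raise ValueError(f"case {self.case_id!r}: followed-up case needs a final diagnosis")
            if self.final_dx.canonical not in FINAL_CATEGORIES:
                raise ValueError(
                    f"case {self.case_id!r}: {self.final_dx.canonical} is not a valid final diagnosis"
                )
        elif self.final_dx is not None:
            raise ValueError(f"case {self.case_id!r}: final diagnosis requires follow-up")


def finals_from_cases(cases: Iterable[CaseRecord]) -> dict[str, DiagnosisLabel]:
    """Reference diagnoses of the followed-up cases, keyed by case id."""
    finals: dict[str, DiagnosisLabel] = {}
    for c in cases:
        if c.case_id in finals:
            raise ValueError(f"duplicate case record {c.case_id!r}")
        if c.followed_up:
            finals[c.case_id] = c.final_dx  # type: ignore[assignment]
    return finals


# ---------------------------------------------------------------------------
# rater selectors

RaterSelector = Callable[[RaterInfo], bool]


def by_group(*groups: Group) -> RaterSelector:
    gs = frozenset(groups)
    return lambda r: r.group in gs


def by_specialty(*specialties: Specialty) -> RaterSelector:
    ss = frozenset(specialties)
    return lambda r: r.specialty in ss


def all_raters(_: RaterInfo) -> bool:
    return True


# ---------------------------------------------------------------------------
# cohort validation


@dataclass
class ValidationReport:
    """Completeness and referential-integrity report for a cohort.

    A cohort passes iff every rater assessed every case exactly once and
    every assessment refers to a known case.
    """

    n_raters: int
    n_cases: int
    n_assessments: int
    missing_pairs: list[tuple[str, str]] = field(default_factory=list)
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    orphan_assessments: list[tuple[str, str]] = field(default_factory=list)
    cases_without_final: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.missing_pairs or self.duplicate_pairs or self.orphan_assessments)

    def summary(self) -> str:
        lines = [
            f"cohort: {self.n_raters} raters x {self.n_cases} cases, "
            f"{self.n_assessments} assessments -> {'PASS' if self.ok else 'FAIL'}"
        ]
        if self.missing_pairs:
            lines.append(f"  missing (rater, case) pairs: {self.missing_pairs[:10]}"
                         + (" ..." if len(self.missing_pairs) > 10 else ""))
        if self.duplicate_pairs:
            lines.append(f"  duplicated (rater, case) pairs: {self.duplicate_pairs[:10]}")
        if self.orphan_assessments:
            lines.append(f"  orphan assessments (unknown case): {self.orphan_assessments[:10]}")
        if self.cases_without_final:
            lines.append(f"  cases without final diagnosis (lost to follow-up): "
                         f"{self.cases_without_final}")
        return "\n".join(lines)


def validate_cohort(
    assessments: Sequence[Assessment], cases: Sequence[CaseRecord]
) -> ValidationReport:
    """Check that every rater assessed every known case exactly once."""
    case_ids = [c.case_id for c in cases]
    case_set = set(case_ids)
    raters = {a.rater.rater_id for a in assessments}

    seen: dict[tuple[str, str], int] = {}
    orphans: list[tuple[str, str]] = []
    for a in assessments:
        key = (a.rater.rater_id, a.case_id)
        seen[key] = seen.get(key, 0) + 1
        if a.case_id not in case_set:
            orphans.append(key)

    missing = [
        (r, c) for r in sorted(raters) for c in case_ids if (r, c) not in seen
    ]
    duplicates = sorted(k for k, n in seen.items() if n > 1)
    no_final = [c.case_id for c in cases if not c.followed_up]

    return ValidationReport(
        n_raters=len(raters),
        n_cases=len(case_ids),
        n_assessments=len(assessments),
        missing_pairs=missing,
        duplicate_pairs=duplicates,
        orphan_assessments=sorted(set(orphans)),
        cases_without_final=no_final,
    )
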