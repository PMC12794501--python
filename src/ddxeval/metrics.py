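"""Evaluation statistics for differential-diagnosis lists.

The central quantity is the Diagnostic Precision Score (DPS).  Per
assessment,

    score = hit − q · n_incorrect

where ``hit`` is 1 if the adjudicated final diagnosis appears anywhere in
the rater's Phase-1 differential and 0 otherwise, ``n_incorrect`` is the
number of listed diagnoses that are not the final diagnosis, and the
penalty ``q`` is calibrated cohort-wide as

    q = 1 / (L_max − 1),

the reciprocal of the largest possible number of *incorrect* diagnoses in
a single list, ``L_max`` being the longest differential observed across
all raters.  With the observed maximum of five diagnoses per list the
penalty is 0.25.  An abstention (empty differential) scores 0: nothing
ventured, nothing penalized.  A group's DPS is the mean per-assessment
score, reported as a percentage.

Cases adjudicated *unexplained* stay in the denominator — the hit is
simply impossible, so every listed diagnosis is incorrect.

Alongside the DPS the module computes diagnostic yield (any diagnosis
proposed), the inclusion rate (final diagnosis present in the list, the
accuracy measure), two-directional diagnostic-safety cross-tabulations
for cardiac syncope, and guideline risk aggregation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .data import (
    Assessment,
    RaterSelector,
    RiskFeatureSet,
    RiskLevel,
)
from .labels import Category, DiagnosisLabel
from .inference import wald_ci

__all__ = [
    "MetricResult",
    "PenaltySource",
    "PenaltyScheme",
    "PenaltyUndefinedError",
    "SafetyDirection",
    "SafetyMode",
    "SafetyCrossTab",
    "RiskClass",
    "calibrate_penalty",
    "score_assessment",
    "diagnostic_yield",
    "multi_diagnosis_rate",
    "inclusion_rate",
    "group_dps",
    "dps_by_case",
    "safety_forward",
    "safety_backward",
    "classify_case_risk",
    "RiskFeatureSet",
    "RiskLevel",
]


@dataclass(frozen=True)
class MetricResult:
    """A proportion-style estimate with its provenance.

    ``estimate`` is on the percentage scale and always equals
    ``100 * numerator / denominator``; confidence bounds, when present,
    are percentages too.  The numerator is a real number because the DPS
    numerator is a sum of scores, not a count.
    """

    estimate: float
    numerator: float
    denominator: int
    ci_low: float | None = None
    ci_high: float | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")
        expected = 100.0 * self.numerator / self.denominator
        if abs(expected - self.estimate) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError(
                f"estimate {self.estimate} inconsistent with "
                f"{self.numerator}/{self.denominator}"
            )

    @classmethod
    def from_counts(
        cls,
        numerator: float,
        denominator: int,
        conf: float | None = None,
        group: str | None = None,
    ) -> "MetricResult":
        ci_low = ci_high = None
        if conf is not None:
            ci_low, ci_high = wald_ci(numerator, denominator, conf)
        return cls(
            estimate=100.0 * numerator / denominator,
            numerator=numerator,
            denominator=denominator,
            ci_low=ci_low,
            ci_high=ci_high,
            group=group,
        )

    def __str__(self) -> str:
        s = f"{self.estimate:.1f}% ({self.numerator:g}/{self.denominator})"
        if self.ci_low is not None:
            s += f" [95% CI {self.ci_low:.1f}-{self.ci_high:.1f}]"
        return s


class PenaltySource(str, enum.Enum):
    CALIBRATED = "CALIBRATED"
    FIXED = "FIXED"


class PenaltyUndefinedError(ValueError):
    """Calibration impossible: no differential with two or more items."""


@dataclass(frozen=True)
class PenaltyScheme:
    """Per-incorrect-diagnosis penalty and the list maximum behind it."""

    penalty: float
    max_list_len: int
    source: PenaltySource = PenaltySource.FIXED

    def __post_init__(self) -> None:
        if not (0.0 < self.penalty <= 1.0):
            raise ValueError("penalty must be in (0, 1]")
        if self.source is PenaltySource.CALIBRATED:
            if self.max_list_len < 2:
                raise ValueError("calibrated scheme needs max_list_len >= 2")
            expected = 1.0 / (self.max_list_len - 1)
            if abs(expected - self.penalty) > 1e-12:
                raise ValueError("calibrated penalty must equal 1/(max_list_len - 1)")

    @classmethod
    def calibrated(cls, max_list_len: int) -> "PenaltyScheme":
        if max_list_len < 2:
            raise PenaltyUndefinedError(
                "penalty undefined: longest differential has fewer than 2 diagnoses"
            )
        return cls(1.0 / (max_list_len - 1), max_list_len, PenaltySource.CALIBRATED)

    @classmethod
    def fixed(cls, penalty: float, max_list_len: int = 5) -> "PenaltyScheme":
        return cls(penalty, max_list_len, PenaltySource.FIXED)


def calibrate_penalty(assessments: Iterable[Assessment]) -> PenaltyScheme:
    """Calibrate the penalty from the longest differential cohort-wide.

    All raters are pooled.  Raises :class:`PenaltyUndefinedError` when
    every list has at most one diagnosis (callers may then supply a
    :meth:`PenaltyScheme.fixed` scheme instead).
    """
    max_len = max((len(a.differential) for a in assessments), default=0)
    return PenaltyScheme.calibrated(max_len)


def score_assessment(
    assessment: Assessment, final: DiagnosisLabel, scheme: PenaltyScheme
) -> float:
    """Score one assessment against the final diagnosis.

    +1 for including the final diagnosis, minus ``penalty`` per incorrect
    listed diagnosis; an empty differential scores 0.  For a final
    diagnosis of ``UNEXPLAINED`` a hit is impossible and every listed
    diagnosis counts as incorrect.
    """
    if final.canonical is Category.NONE:
        raise ValueError("final diagnosis cannot be NONE; use UNEXPLAINED")
    n = len(assessment.differential)
    if n == 0:
        return 0.0
    hit = int(final.canonical in assessment.categories)
    return hit - scheme.penalty * (n - hit)


def _select(assessments: Iterable[Assessment], selector: RaterSelector) -> list[Assessment]:
    chosen = [a for a in assessments if selector(a.rater)]
    if not chosen:
        raise ValueError("selection matches no assessments")
    return chosen


def _eligible(
    assessments: Iterable[Assessment],
    finals: Mapping[str, DiagnosisLabel],
    selector: RaterSelector,
) -> list[Assessment]:
    chosen = [a for a in _select(assessments, selector) if a.case_id in finals]
    if not chosen:
        raise ValueError("selection matches no assessments of followed-up cases")
    return chosen


def diagnostic_yield(
    assessments: Iterable[Assessment],
    selector: RaterSelector,
    conf: float | None = None,
    group: str | None = None,
) -> MetricResult:
    """Proportion of assessments proposing at least one diagnosis.

    Computed over *all* assessed cases, including any later lost to
    follow-up: yield is a Phase-1 quantity.
    """
    chosen = _select(assessments, selector)
    hits = sum(not a.abstained for a in chosen)
    return MetricResult.from_counts(hits, len(chosen), conf=conf, group=group)


def multi_diagnosis_rate(
    assessments: Iterable[Assessment],
    selector: RaterSelector,
    conf: float | None = None,
    group: str | None = None,
) -> MetricResult:
    """Proportion of assessments proposing more than one diagnosis."""
    chosen = _select(assessments, selector)
    multi = sum(len(a.differential) >= 2 for a in chosen)
    return MetricResult.from_counts(multi, len(chosen), conf=conf, group=group)


def inclusion_rate(
    assessments: Iterable[Assessment],
    finals: Mapping[str, DiagnosisLabel],
    selector: RaterSelector,
    conf: float = 0.95,
    group: str | None = None,
) -> MetricResult:
    """Proportion of eligible assessments whose list contains the final
    diagnosis, with a Wald confidence interval.

    Only followed-up cases are eligible; an ``UNEXPLAINED`` final can
    never be included, so those assessments count as misses.
    """
    chosen = _eligible(assessments, finals, selector)
    hits = sum(
        finals[a.case_id].canonical in a.categories for a in chosen
    )
    return MetricResult.from_counts(hits, len(chosen), conf=conf, group=group)


def group_dps(
    assessments: Iterable[Assessment],
    finals: Mapping[str, DiagnosisLabel],
    scheme: PenaltyScheme,
    selector: RaterSelector,
    group: str | None = None,
) -> MetricResult:
    """Mean per-assessment precision score over a selection, as a
    percentage (may be negative)."""
    chosen = _eligible(assessments, finals, selector)
    total = sum(score_assessment(a, finals[a.case_id], scheme) for a in chosen)
    return MetricResult.from_counts(total, len(chosen), group=group)


def dps_by_case(
    assessments: Iterable[Assessment],
    finals: Mapping[str, DiagnosisLabel],
    scheme: PenaltyScheme,
    selector: RaterSelector,
) -> dict[str, float]:
    """Per-case DPS: mean score across the selected raters, by case.

    This is the per-case aggregation the group comparison uses (each
    followed-up case contributes one value per group).
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for a in _eligible(assessments, finals, selector):
        s = score_assessment(a, finals[a.case_id], scheme)
        sums[a.case_id] = sums.get(a.case_id, 0.0) + s
        counts[a.case_id] = counts.get(a.case_id, 0) + 1
    return {cid: sums[cid] / counts[cid] for cid in sums}


# ---------------------------------------------------------------------------
# diagnostic safety


class SafetyDirection(str, enum.Enum):
    FORWARD = "FORWARD"
    BACKWARD = "BACKWARD"


class SafetyMode(str, enum.Enum):
    """What counts as a Phase-1 cardiac call in the forward direction.

    ``FIRST_LISTED``: the rank-1 diagnosis is cardiac, regardless of list
    length (used for AI-style raters that always produce a ranked list).
    ``SINGLE_ONLY``: the list is exactly one diagnosis and it is cardiac;
    multi-diagnosis assessments are excluded.
    """

    FIRST_LISTED = "FIRST_LISTED"
    SINGLE_ONLY = "SINGLE_ONLY"


#: Backward-direction response classes for final-cardiac cases.
CARDIAC_SINGLE = "CARDIAC_SINGLE"
WITHIN_MULTIPLE = "WITHIN_MULTIPLE"
NO_DIAGNOSIS = "NO_DIAGNOSIS"


@dataclass(frozen=True)
class SafetyCrossTab:
    """Cross-tabulation of cardiac-syncope recognition.

    Forward: Phase-1 cardiac calls broken down by the final diagnosis
    class they turned out to have.  Backward: Phase-1 responses to
    final-cardiac cases, classified by how (whether) cardiac appeared.
    """

    direction: SafetyDirection
    counts: Mapping[str, int]
    total: int
    group: str | None = None

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("cross-tab counts must sum to total")

    def proportion(self, category: str) -> float:
        if self.total == 0:
            return 0.0
        return 100.0 * self.counts.get(category, 0) / self.total

    def miss_rate(self) -> float:
        """Backward only: percentage of final-cardiac responses in which
        cardiac appeared nowhere in the Phase-1 list."""
        if self.direction is not SafetyDirection.BACKWARD:
            raise ValueError("miss rate is defined for the backward direction")
        recognized = self.counts.get(CARDIAC_SINGLE, 0) + self.counts.get(WITHIN_MULTIPLE, 0)
        return 100.0 * (self.total - recognized) / self.total


def safety_forward(
    assessments: Iterable[Assessment],
    finals: Mapping[str, DiagnosisLabel],
    selector: RaterSelector,
    mode: SafetyMode,
    group: str | None = None,
) -> SafetyCrossTab:
    """Verify Phase-1 cardiac calls against the final diagnoses."""
    counts: dict[str, int] = {}
    total = 0
    for a in _eligible(assessments, finals, selector):
        if a.abstained:
            continue
        if mode is SafetyMode.SINGLE_ONLY:
            called = len(a.differential) == 1 and a.differential[0].canonical is Category.CARDIAC
        else:
            called = a.differential[0].canonical is Category.CARDIAC
        if not called:
            continue
        key = finals[a.case_id].canonical.value
        counts[key] = counts.get(key, 0) + 1
        total += 1
    return SafetyCrossTab(SafetyDirection.FORWARD, counts, total, group=group)


def safety_backward(
    assessments: Iterable[Assessment],
    finals: Mapping[str, DiagnosisLabel],
    selector: RaterSelector,
    group: str | None = None,
) -> SafetyCrossTab:
    """Classify Phase-1 responses to the final-cardiac cases.

    Per (rater, final-cardiac case) pair: ``CARDIAC_SINGLE`` for a
    single cardiac diagnosis, ``WITHIN_MULTIPLE`` when cardiac appears
    in a list of two or more, ``NO_DIAGNOSIS`` for an abstention, and
    otherwise the rank-1 (first-proposed) non-cardiac category.
    """
    cardiac_cases = {
        cid for cid, dx in finals.items() if dx.canonical is Category.CARDIAC
    }
    if not cardiac_cases:
        raise ValueError("no reference cardiac cases in the cohort")
    counts: dict[str, int] = {}
    total = 0
    for a in _select(assessments, selector):
        if a.case_id not in cardiac_cases:
            continue
        if a.abstained:
            key = NO_DIAGNOSIS
        elif Category.CARDIAC in a.categories:
            key = CARDIAC_SINGLE if len(a.differential) == 1 else WITHIN_MULTIPLE
        else:
            key = a.differential[0].canonical.value
        counts[key] = counts.get(key, 0) + 1
        total += 1
    return SafetyCrossTab(SafetyDirection.BACKWARD, counts, total, group=group)


# ---------------------------------------------------------------------------
# guideline risk aggregation


class RiskClass(str, enum.Enum):
    HIGH = "HIGH"
    HIGH_MINOR_ONLY = "HIGH_MINOR_ONLY"
    LOW = "LOW"
    UNCLASSIFIABLE = "UNCLASSIFIABLE"

    def __str__(self) -> str:
        return self.value


def classify_case_risk(features: RiskFeatureSet) -> RiskClass:
    """Aggregate per-domain risk features into a case-level class.

    High risk: any high-major feature, or at least one high-minor
    feature in the presence of structural heart disease.  A high-minor
    feature without structural heart disease is flagged separately; a
    letter documenting only low-risk features is low risk; a letter
    mentioning none of the domains is unclassifiable.
    """
    domains = features.domains
    if any(d is RiskLevel.HIGH_MAJOR for d in domains):
        return RiskClass.HIGH
    if any(d is RiskLevel.HIGH_MINOR for d in domains):
        return RiskClass.HIGH if features.structural_heart_disease else RiskClass.HIGH_MINOR_ONLY
    if any(d is RiskLevel.LOW for d in domains):
        return RiskClass.LOW
    return RiskClass.UNCLASSIFIABLE
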