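"""Committee adjudication of the reference (final) diagnosis.

After follow-up, each committee member independently reviews a case and
either proposes a diagnosis or abstains (``NONE``).  The automatic rules
are deliberately narrow:

* all members agree on the same diagnosis  -> ``UNANIMOUS``;
* all but one agree and that one abstained -> ``MAJORITY_WITH_ABSTAIN``;
* anything else goes to a face-to-face consensus meeting; if the meeting
  produces a diagnosis the rule is ``CONSENSUS_MEETING``, otherwise the
  case is deemed ``UNEXPLAINED``.

Two identical opinions plus one *different* (non-abstaining) diagnosis is
a disagreement and goes to the meeting — the automatic majority rule only
covers abstention of the remaining member.  Likewise two abstentions plus
a single diagnosis is meeting-required, not an automatic majority.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .labels import Category, DIFFERENTIAL_CATEGORIES, DiagnosisLabel

__all__ = [
    "AdjudicationRule",
    "ReviewerOpinion",
    "AdjudicationResult",
    "MeetingNotReachableError",
    "adjudicate",
    "adjudicate_cases",
]


class AdjudicationRule(str, enum.Enum):
    UNANIMOUS = "UNANIMOUS"
    MAJORITY_WITH_ABSTAIN = "MAJORITY_WITH_ABSTAIN"
    CONSENSUS_MEETING = "CONSENSUS_MEETING"
    UNEXPLAINED = "UNEXPLAINED"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class ReviewerOpinion:
    """One committee member's independent diagnosis (``NONE`` = none)."""

    reviewer_id: str
    dx: DiagnosisLabel

    def __post_init__(self) -> None:
        if self.dx.canonical not in DIFFERENTIAL_CATEGORIES | {Category.NONE}:
            raise ValueError(
                f"reviewer {self.reviewer_id!r}: {self.dx.canonical} is not a valid opinion"
            )

    @property
    def abstained(self) -> bool:
        return self.dx.canonical is Category.NONE


@dataclass(frozen=True)
class AdjudicationResult:
    final_dx: DiagnosisLabel
    rule: AdjudicationRule


class MeetingNotReachableError(ValueError):
    """A meeting outcome was supplied although an automatic rule resolves."""


def adjudicate(
    opinions: Sequence[ReviewerOpinion],
    meeting_outcome: DiagnosisLabel | None = None,
    committee_size: int = 3,
) -> AdjudicationResult:
    """Apply the committee rules to one case.

    Parameters
    ----------
    opinions
        Exactly ``committee_size`` independent reviewer opinions.
    meeting_outcome
        Diagnosis established in the consensus meeting; supply only when
        the automatic rules do not resolve the case.
    committee_size
        Committee size (>= 3).  The rules generalize as "all agree",
        "all but one agree and that one abstained", else meeting.

    The result is invariant under permutation of the opinions.
    """
    if committee_size < 3:
        raise ValueError("committee size must be >= 3")
    if len(opinions) != committee_size:
        raise ValueError(
            f"expected {committee_size} opinions, got {len(opinions)}"
        )

    named = [o.dx for o in opinions if not o.abstained]
    n_abstain = len(opinions) - len(named)
    distinct = {d.canonical for d in named}

    if not named:
        # nothing on the table: no meeting reachable from zero diagnoses
        if meeting_outcome is not None:
            raise MeetingNotReachableError("all reviewers abstained; case is unexplained")
        return AdjudicationResult(DiagnosisLabel.of(Category.UNEXPLAINED), AdjudicationRule.UNEXPLAINED)

    if len(distinct) == 1 and n_abstain <= 1:
        if meeting_outcome is not None:
            raise MeetingNotReachableError("automatic rule resolves this case; meeting not reachable")
        rule = (
            AdjudicationRule.UNANIMOUS
            if n_abstain == 0
            else AdjudicationRule.MAJORITY_WITH_ABSTAIN
        )
        return AdjudicationResult(named[0], rule)

    # disagreement (or too many abstentions): consensus meeting decides
    if meeting_outcome is None or meeting_outcome.canonical is Category.NONE:
        return AdjudicationResult(DiagnosisLabel.of(Category.UNEXPLAINED), AdjudicationRule.UNEXPLAINED)
    return AdjudicationResult(meeting_outcome, AdjudicationRule.CONSENSUS_MEETING)


def adjudicate_cases(
    opinions_by_case: Mapping[str, Sequence[ReviewerOpinion]],
    meeting_outcomes: Mapping[str, DiagnosisLabel] | None = None,
    committee_size: int = 3,
) -> dict[str, AdjudicationResult]:
    """Adjudicate every case in a committee opinions table."""
    meeting_outcomes = meeting_outcomes or {}
    return {
        case_id: adjudicate(
            list(ops),
            meeting_outcome=meeting_outcomes.get(case_id),
            committee_size=committee_size,
        )
        for case_id, ops in opinions_by_case.items()
    }
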