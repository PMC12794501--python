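"""Readers and writers for the tidy cohort tables.

Three delimited tables describe a cohort:

``assessments.csv``
    one row per proposed diagnosis per rater per case, columns
    ``case_id, rater_id, rater_group, rater_specialty, rank, diagnosis,
    n_questions, n_tests_suggested, n_interventions_suggested``.
    An abstention is a single row with ``rank`` 0 and an empty
    ``diagnosis`` field — explicit, so "no diagnosis established" is
    distinguishable from "not yet entered".

``cases.csv``
    ``case_id, final_dx, followed_up`` plus optional risk-feature
    columns ``risk_event, risk_history, risk_exam, risk_ecg,
    structural_heart_disease``.

``opinions.csv`` / ``meeting.csv``
    committee reviewer opinions (``case_id, reviewer_id, diagnosis``,
    empty diagnosis = no diagnosis) and consensus-meeting outcomes.

The writers emit a canonical form of the same dialect; reading a
canonical file and writing it back reproduces it byte for byte.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .adjudication import ReviewerOpinion
from .data import (
    Assessment,
    CaseRecord,
    Group,
    RaterInfo,
    RiskFeatureSet,
    RiskLevel,
    Specialty,
)
from .labels import Category, DiagnosisLabel, SynonymMap, canonicalize_label

__all__ = [
    "CohortFormatError",
    "ASSESSMENT_COLUMNS",
    "read_assessments",
    "write_assessments",
    "read_cases",
    "write_cases",
    "read_opinions",
    "read_meeting_outcomes",
    "read_synonyms",
]


class CohortFormatError(ValueError):
    """An input table violates the cohort CSV dialect."""


ASSESSMENT_COLUMNS = [
    "case_id",
    "rater_id",
    "rater_group",
    "rater_specialty",
    "rank",
    "diagnosis",
    "n_questions",
    "n_tests_suggested",
    "n_interventions_suggested",
]

_CASE_COLUMNS = ["case_id", "final_dx", "followed_up"]
_RISK_COLUMNS = ["risk_event", "risk_history", "risk_exam", "risk_ecg",
                 "structural_heart_disease"]


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing columns {missing}")
    return df


def _parse_enum(enum_cls, token: str, what: str, where: str):
    try:
        return enum_cls(token)
    except ValueError:
        raise CohortFormatError(f"{where}: unknown {what} token {token!r}") from None


def read_synonyms(path) -> SynonymMap:
    """Load a synonym map, layered on top of the built-in spellings."""
    return SynonymMap.from_yaml(path)


# ---------------------------------------------------------------------------
# assessments


def read_assessments(
    path,
    synonym_map: SynonymMap | None = None,
    max_list: int = 5,
) -> list[Assessment]:
    """Read and validate an assessments table.

    Rows are grouped by ``(case_id, rater_id)``; within a group ranks
    must be 1..k contiguous (or a single rank-0 abstention row).
    Violations — duplicate ranks, rank gaps, lists longer than
    ``max_list``, unknown group/specialty tokens — raise
    :class:`CohortFormatError`.
    """
    synonym_map = synonym_map or SynonymMap.default()
    df = _read_table(path, ASSESSMENT_COLUMNS)
    out: list[Assessment] = []
    for (case_id, rater_id), rows in df.groupby(["case_id", "rater_id"], sort=False):
        where = f"(case {case_id}, rater {rater_id})"
        first = rows.iloc[0]
        rater = RaterInfo(
            rater_id=rater_id,
            group=_parse_enum(Group, first["rater_group"], "group", where),
            specialty=_parse_enum(Specialty, first["rater_specialty"], "specialty", where),
        )
        try:
            ranks = [int(r) for r in rows["rank"]]
        except ValueError as exc:
            raise CohortFormatError(f"{where}: non-integer rank ({exc})") from None
        if len(set(ranks)) != len(ranks):
            raise CohortFormatError(f"{where}: duplicate rank")
        if ranks == [0]:
            if first["diagnosis"].strip():
                raise CohortFormatError(f"{where}: abstention row (rank 0) must have empty diagnosis")
            differential: tuple[DiagnosisLabel, ...] = ()
        else:
            if 0 in ranks:
                raise CohortFormatError(f"{where}: rank-0 abstention row mixed with ranked rows")
            if sorted(ranks) != list(range(1, len(ranks) + 1)):
                raise CohortFormatError(f"{where}: rank gap (got ranks {sorted(ranks)})")
            if len(ranks) > max_list:
                raise CohortFormatError(
                    f"{where}: differential longer than maximum ({len(ranks)} > {max_list})"
                )
            ordered = rows.assign(_rank=ranks).sort_values("_rank")
            labels = []
            for text in ordered["diagnosis"]:
                if not text.strip():
                    raise CohortFormatError(f"{where}: empty diagnosis at non-zero rank")
                labels.append(canonicalize_label(text, synonym_map))
            differential = tuple(labels)
        try:
            out.append(
                Assessment(
                    case_id=case_id,
                    rater=rater,
                    differential=differential,
                    n_questions=int(first["n_questions"] or 0),
                    n_tests_suggested=int(first["n_tests_suggested"] or 0),
                    n_interventions_suggested=int(first["n_interventions_suggested"] or 0),
                )
            )
        except ValueError as exc:
            raise CohortFormatError(f"{where}: {exc}") from None
    return out


def write_assessments(assessments: Iterable[Assessment], path) -> None:
    """Write assessments in the canonical dialect (one row per diagnosis)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(ASSESSMENT_COLUMNS)
        for a in assessments:
            base = [
                a.case_id,
                a.rater.rater_id,
                a.rater.group.value,
                a.rater.specialty.value,
            ]
            tail = [a.n_questions, a.n_tests_suggested, a.n_interventions_suggested]
            if a.abstained:
                w.writerow(base + [0, ""] + tail)
            else:
                for rank, d in enumerate(a.differential, start=1):
                    w.writerow(base + [rank, d.raw_text] + tail)


# ---------------------------------------------------------------------------
# cases


def read_cases(path, synonym_map: SynonymMap | None = None) -> list[CaseRecord]:
    """Read case records; risk-feature columns are optional."""
    synonym_map = synonym_map or SynonymMap.default()
    df = _read_table(path, _CASE_COLUMNS)
    has_risk = all(c in df.columns for c in _RISK_COLUMNS)
    out: list[CaseRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        cid = row["case_id"]
        if cid in seen:
            raise CohortFormatError(f"duplicate case record {cid!r}")
        seen.add(cid)
        followed = row["followed_up"].strip().lower() in {"true", "1", "yes"}
        final = None
        if followed:
            if not row["final_dx"].strip():
                raise CohortFormatError(f"case {cid!r}: followed up but final_dx empty")
            final = canonicalize_label(row["final_dx"], synonym_map)
        elif row["final_dx"].strip():
            raise CohortFormatError(f"case {cid!r}: final_dx given without follow-up")
        risk = None
        if has_risk:
            risk = RiskFeatureSet(
                event=_parse_enum(RiskLevel, row["risk_event"], "risk level", cid),
                history=_parse_enum(RiskLevel, row["risk_history"], "risk level", cid),
                exam=_parse_enum(RiskLevel, row["risk_exam"], "risk level", cid),
                ecg=_parse_enum(RiskLevel, row["risk_ecg"], "risk level", cid),
                structural_heart_disease=row["structural_heart_disease"].strip().lower()
                in {"true", "1", "yes"},
            )
        out.append(CaseRecord(case_id=cid, final_dx=final, followed_up=followed, risk=risk))
    return out


def write_cases(cases: Iterable[CaseRecord], path) -> None:
    cases = list(cases)
    with_risk = any(c.risk is not None for c in cases)
    cols = _CASE_COLUMNS + (_RISK_COLUMNS if with_risk else [])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for c in cases:
            row = [
                c.case_id,
                c.final_dx.raw_text if c.final_dx is not None else "",
                "true" if c.followed_up else "false",
            ]
            if with_risk:
                r = c.risk or RiskFeatureSet()
                row += [
                    r.event.value,
                    r.history.value,
                    r.exam.value,
                    r.ecg.value,
                    "true" if r.structural_heart_disease else "false",
                ]
            w.writerow(row)


# ---------------------------------------------------------------------------
# committee tables


def read_opinions(path, synonym_map: SynonymMap | None = None) -> dict[str, list[ReviewerOpinion]]:
    """Read reviewer opinions grouped by case; empty diagnosis = NONE."""
    synonym_map = synonym_map or SynonymMap.default()
    df = _read_table(path, ["case_id", "reviewer_id", "diagnosis"])
    out: dict[str, list[ReviewerOpinion]] = {}
    for _, row in df.iterrows():
        text = row["diagnosis"].strip()
        dx = (
            DiagnosisLabel(Category.NONE, raw_text=row["diagnosis"])
            if not text
            else canonicalize_label(row["diagnosis"], synonym_map)
        )
        out.setdefault(row["case_id"], []).append(
            ReviewerOpinion(reviewer_id=row["reviewer_id"], dx=dx)
        )
    return out


def read_meeting_outcomes(path, synonym_map: SynonymMap | None = None) -> dict[str, DiagnosisLabel]:
    """Read consensus-meeting outcomes, keyed by case id."""
    synonym_map = synonym_map or SynonymMap.default()
    df = _read_table(path, ["case_id", "meeting_diagnosis"])
    out: dict[str, DiagnosisLabel] = {}
    for _, row in df.iterrows():
        if row["case_id"] in out:
            raise CohortFormatError(f"duplicate meeting outcome for case {row['case_id']!r}")
        if row["meeting_diagnosis"].strip():
            out[row["case_id"]] = canonicalize_label(row["meeting_diagnosis"], synonym_map)
    return out
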