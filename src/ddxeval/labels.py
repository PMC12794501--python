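"""Canonical diagnosis categories and free-text label handling.

Syncope diagnoses are coarse-grained into a closed set of categories:
reflex (vasovagal) syncope, orthostatic hypotension, cardiac syncope,
psychogenic pseudosyncope, and a catch-all ``OTHER``.  Two sentinels
complete the set: ``NONE`` marks an abstention (a rater or committee
member who established no diagnosis) and ``UNEXPLAINED`` is reserved for
adjudicated final diagnoses where the committee reached no consensus.

Free-text diagnosis strings are mapped onto the canonical set through a
:class:`SynonymMap`.  The mapping is deliberately explicit: a string with
no entry raises :class:`UnmappedLabelError` rather than being guessed,
because which arrhythmias count as "cardiac", say, is a study-level
decision that belongs in an editable configuration file.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

__all__ = [
    "Category",
    "DIFFERENTIAL_CATEGORIES",
    "FINAL_CATEGORIES",
    "DiagnosisLabel",
    "SynonymMap",
    "UnmappedLabelError",
    "canonicalize_label",
    "normalize_text",
]


class Category(str, enum.Enum):
    """Closed set of canonical diagnosis categories."""

    REFLEX = "REFLEX"
    ORTHOSTATIC_HYPOTENSION = "ORTHOSTATIC_HYPOTENSION"
    CARDIAC = "CARDIAC"
    PSYCHOGENIC_PSEUDOSYNCOPE = "PSYCHOGENIC_PSEUDOSYNCOPE"
    OTHER = "OTHER"
    NONE = "NONE"
    UNEXPLAINED = "UNEXPLAINED"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


#: Categories that may appear inside a (non-empty) differential list.
DIFFERENTIAL_CATEGORIES = frozenset(
    {
        Category.REFLEX,
        Category.ORTHOSTATIC_HYPOTENSION,
        Category.CARDIAC,
        Category.PSYCHOGENIC_PSEUDOSYNCOPE,
        Category.OTHER,
    }
)

#: Categories a committee-adjudicated final diagnosis may take.
FINAL_CATEGORIES = DIFFERENTIAL_CATEGORIES | {Category.UNEXPLAINED}

_WS = re.compile(r"\s+")


def normalize_text(raw: str) -> str:
    """Casefold and collapse internal whitespace for synonym lookup."""
    return _WS.sub(" ", raw.strip()).casefold()


class UnmappedLabelError(KeyError):
    """A free-text diagnosis string has no synonym-map entry."""

    def __init__(self, raw: str):
        super().__init__(raw)
        self.raw = raw

    def __str__(self) -> str:
        return f"unmapped label: {self.raw!r}"


@dataclass(frozen=True)
class DiagnosisLabel:
    """A canonical category together with the verbatim source string."""

    canonical: Category
    raw_text: str = ""

    def __post_init__(self) -> None:
        if not self.raw_text:
            object.__setattr__(self, "raw_text", self.canonical.value)

    @classmethod
    def of(cls, category: Category | str) -> "DiagnosisLabel":
        """Build a label directly from a canonical category."""
        return cls(Category(category))


# Spellings recognised out of the box.  Everything beyond these ships in
# an editable synonyms.yaml; nothing is ever guessed at lookup time.
_BUILTIN_SYNONYMS: dict[str, Category] = {
    "reflex": Category.REFLEX,
    "reflex syncope": Category.REFLEX,
    "vasovagal": Category.REFLEX,
    "vasovagal syncope": Category.REFLEX,
    "orthostatic hypotension": Category.ORTHOSTATIC_HYPOTENSION,
    "orthostatic_hypotension": Category.ORTHOSTATIC_HYPOTENSION,
    "oh": Category.ORTHOSTATIC_HYPOTENSION,
    "cardiac": Category.CARDIAC,
    "cardiac syncope": Category.CARDIAC,
    "psychogenic pseudosyncope": Category.PSYCHOGENIC_PSEUDOSYNCOPE,
    "psychogenic_pseudosyncope": Category.PSYCHOGENIC_PSEUDOSYNCOPE,
    "pps": Category.PSYCHOGENIC_PSEUDOSYNCOPE,
    "other": Category.OTHER,
    "unexplained": Category.UNEXPLAINED,
    "unexplained syncope": Category.UNEXPLAINED,
}


@dataclass(frozen=True)
class SynonymMap:
    """Explicit mapping from normalized free text to canonical categories.

    Lookup is case-insensitive and whitespace-normalized.  Unknown
    strings raise :class:`UnmappedLabelError`; they are never silently
    mapped to ``OTHER``.
    """

    entries: Mapping[str, Category] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized = {normalize_text(k): Category(v) for k, v in self.entries.items()}
        object.__setattr__(self, "entries", normalized)

    @classmethod
    def default(cls) -> "SynonymMap":
        """Map containing only the built-in canonical spellings."""
        return cls(dict(_BUILTIN_SYNONYMS))

    @classmethod
    def from_yaml(cls, path) -> "SynonymMap":
        """Load ``raw string -> CATEGORY`` entries from a YAML mapping.

        Entries extend (and may override) the built-in spellings.
        """
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"synonym file {path!s} must contain a mapping")
        merged = dict(_BUILTIN_SYNONYMS)
        merged.update({str(k): Category(str(v).upper()) for k, v in data.items()})
        return cls(merged)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {k: v.value for k, v in sorted(self.entries.items())},
                fh,
                sort_keys=True,
            )

    def lookup(self, raw: str) -> Category:
        key = normalize_text(raw)
        try:
            return self.entries[key]
        except KeyError:
            raise UnmappedLabelError(raw) from None

    def __contains__(self, raw: str) -> bool:
        return normalize_text(raw) in self.entries


def canonicalize_label(raw: str, synonym_map: SynonymMap | None = None) -> DiagnosisLabel:
    """Map a free-text diagnosis to a :class:`DiagnosisLabel`.

    Parameters
    ----------
    raw
        Non-empty diagnosis text as written by the rater.
    synonym_map
        Mapping to use; defaults to :meth:`SynonymMap.default`.

    Raises
    ------
    UnmappedLabelError
        If the normalized string has no entry.
    ValueError
        If ``raw`` is empty (an abstention is an empty differential, not
        an empty label).
    """
    if not raw or not raw.strip():
        raise ValueError("diagnosis text must be non-empty; encode abstention as an empty differential")
    synonym_map = synonym_map or SynonymMap.default()
    return DiagnosisLabel(synonym_map.lookup(raw), raw_text=raw)
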