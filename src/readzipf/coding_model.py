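"""Data model for 5-byte hierarchical clinical (Read v2 style) codes.

A code is a string of 1-5 alphanumeric characters.  Each character encodes
one level of the terminology tree, so the *depth* of a code is simply its
length: ``G`` (circulatory system diseases, depth 1) refines to ``G3``
(ischaemic heart disease), ``G30``, ``G301`` and finally ``G3011`` (acute
anteroseptal infarction, depth 5).

The class of the first character determines the *section* the code belongs
to: digits ``0-9`` are processes of care (procedures), uppercase ``A-Z``
are diagnoses, and lowercase ``a-z`` are medication.  Case is therefore
semantically significant and is never folded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

__all__ = [
    "Section",
    "ClinicalCode",
    "Terminology",
    "DepthProfile",
    "MalformedCodeError",
    "EmptyInputError",
    "MAX_DEPTH",
    "parse_code",
    "classify_section",
    "terminology_depth_profile",
    "depth_profiles_from_codes",
    "load_terminology",
]

MAX_DEPTH = 5

_ALNUM = frozenset("0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz")


class MalformedCodeError(ValueError):
    """Raised when a string cannot be parsed as a valid clinical code."""


class EmptyInputError(ValueError):
    """Raised when an operation requires a non-empty collection."""


class Section(enum.Enum):
    """Top-level division of the code space, determined by the first character."""

    PROCESS_OF_CARE = "process_of_care"  # first character 0-9
    DIAGNOSIS = "diagnosis"              # first character A-Z
    MEDICATION = "medication"            # first character a-z

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _section_of_char(ch: str) -> Section:
    if ch.isdigit():
        return Section.PROCESS_OF_CARE
    if ch.isupper():
        return Section.DIAGNOSIS
    return Section.MEDICATION


@dataclass(frozen=True, slots=True)
class ClinicalCode:
    """A validated hierarchical code.

    ``depth`` equals the character count (1-5), ``chapter`` is the first
    character, and ``section`` follows from the chapter's character class.
    Instances are immutable and hashable so they can live in sets and be
    used as dictionary keys.
    """

    text: str

    @property
    def depth(self) -> int:
        return len(self.text)

    @property
    def chapter(self) -> str:
        return self.text[0]

    @property
    def section(self) -> Section:
        return _section_of_char(self.text[0])

    @property
    def parent_text(self) -> str | None:
        """The text of the immediate ancestor, or None for depth-1 codes."""
        return self.text[:-1] if len(self.text) > 1 else None

    def render(self) -> str:
        return self.text

    def __str__(self) -> str:
        return self.text


def parse_code(text: str) -> ClinicalCode:
    """Parse a raw string into a :class:`ClinicalCode`.

    Surrounding whitespace is trimmed and trailing ``.`` filler characters
    (as emitted by some Read v2 export dialects, e.g. ``G30..``) are
    stripped before the depth is computed, so depth always reflects the
    semantic level of the term.  Case is preserved: it carries the section
    semantics.

    Raises
    ------
    MalformedCodeError
        If the string is empty (or all dots), longer than 5 characters, or
        contains a character outside ``[A-Za-z0-9]``.
    """
    if text is None:
        raise MalformedCodeError("code is missing")
    stripped = text.strip()
    core = stripped.rstrip(".")
    if not core:
        raise MalformedCodeError(f"empty or all-filler code: {text!r}")
    if len(core) > MAX_DEPTH:
        raise MalformedCodeError(
            f"code {core!r} has {len(core)} characters; the 5-byte format allows at most {MAX_DEPTH}"
        )
    bad = [ch for ch in core if ch not in _ALNUM]
    if bad:
        raise MalformedCodeError(f"code {core!r} contains invalid character {bad[0]!r}")
    return ClinicalCode(core)


def classify_section(code: ClinicalCode) -> Section:
    """Section of a code: digit chapter -> process of care, uppercase ->
    diagnosis, lowercase -> medication."""
    return code.section


@dataclass(frozen=True)
class Terminology:
    """A (possibly partial) set of codes available to coders.

    ``max_depth_by_section`` records the deepest level the terminology
    offers in each section; in the official Read v2 release medication
    stops at depth 4 while diagnosis and procedure chapters reach depth 5.
    Those ceilings are configuration here, not fact: the official release
    is not distributed with this package.
    """

    codes: frozenset[ClinicalCode]
    max_depth_by_section: Mapping[Section, int] = field(default_factory=dict)
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for section, ceiling in self.max_depth_by_section.items():
            if ceiling > MAX_DEPTH:
                raise ValueError(
                    f"depth ceiling {ceiling} for {section} exceeds the format maximum {MAX_DEPTH}"
                )

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, item: Union[str, ClinicalCode]) -> bool:
        if isinstance(item, str):
            item = ClinicalCode(item)
        return item in self.codes

    def in_section(self, section: Section) -> list[ClinicalCode]:
        return sorted(
            (c for c in self.codes if c.section is section), key=lambda c: c.text
        )


@dataclass(frozen=True)
class DepthProfile:
    """Percentage of codes at each hierarchy level for one group
    (a chapter or a section)."""

    label: str
    percent_at_depth: Mapping[int, float]

    def as_dict(self) -> dict:
        return {"label": self.label, "percent_at_depth": dict(self.percent_at_depth)}


def _profile(label: str, depths: Iterable[int], weights: Iterable[float] | None = None) -> DepthProfile:
    import numpy as np

    depths = np.asarray(list(depths), dtype=int)
    if depths.size == 0:
        raise EmptyInputError(f"no codes in group {label!r}")
    w = np.ones(depths.size) if weights is None else np.asarray(list(weights), dtype=float)
    total = w.sum()
    percent = {}
    for d in range(1, MAX_DEPTH + 1):
        percent[d] = 100.0 * float(w[depths == d].sum()) / total
    return DepthProfile(label, percent)


def depth_profiles_from_codes(
    codes: Iterable[ClinicalCode],
    group_by: str = "chapter",
    weights: Mapping[str, float] | None = None,
) -> list[DepthProfile]:
    """Group codes by chapter or section and profile their depths.

    ``weights`` optionally maps code text to a weight (e.g. a usage count);
    unweighted, each distinct code counts once.
    """
    codes = list(codes)
    if not codes:
        raise EmptyInputError("no codes to profile")
    if group_by not in ("chapter", "section"):
        raise ValueError(f"group_by must be 'chapter' or 'section', got {group_by!r}")
    groups: dict[str, list[ClinicalCode]] = {}
    for c in codes:
        key = c.chapter if group_by == "chapter" else c.section.value
        groups.setdefault(key, []).append(c)
    profiles = []
    for label in sorted(groups):
        members = groups[label]
        w = None if weights is None else [weights.get(c.text, 0.0) for c in members]
        profiles.append(_profile(label, (c.depth for c in members), w))
    return profiles


def terminology_depth_profile(
    term: Terminology, group_by: str = "chapter"
) -> list[DepthProfile]:
    """Depth distribution of the codes a terminology *offers*, per group.

    This is the "codes available" view; contrast with
    :func:`readzipf.corpus_stats.usage_depth_profile`, which profiles the
    codes actually used in a corpus.
    """
    if not term.codes:
        raise EmptyInputError("terminology is empty")
    return depth_profiles_from_codes(term.codes, group_by=group_by)


def load_terminology(path: str | Path) -> Terminology:
    """Load a terminology from a two-column TSV (code, description).

    UTF-8; lines starting with ``#`` are ignored; the description column is
    optional and passed through untouched.
    """
    codes: set[ClinicalCode] = set()
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            code = parse_code(parts[0])
            codes.add(code)
            if len(parts) > 1 and parts[1]:
                descriptions[code.text] = parts[1]
    if not codes:
        raise EmptyInputError(f"no codes found in {path}")
    ceilings: dict[Section, int] = {}
    for c in codes:
        ceilings[c.section] = max(ceilings.get(c.section, 0), c.depth)
    return Terminology(frozenset(codes), ceilings, descriptions)
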