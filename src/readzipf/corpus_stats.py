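"""Corpus ingestion and descriptive statistics for coded clinical events.

An :class:`EncounterCorpus` is an ordered stream of coded events (patient,
practice, date, code).  From it we build a :class:`FrequencyTable` — the
per-code counts with rank-frequency and frequency-of-frequencies views —
which is the sample every downstream power-law fit operates on, plus the
classic corpus-linguistics summaries: type-token ratio (TTR), empirical
Pareto (tail CDF) curves, and depth-of-use profiles.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .coding_model import (
    ClinicalCode,
    DepthProfile,
    EmptyInputError,
    MalformedCodeError,
    Section,
    _profile,
    parse_code,
)

__all__ = [
    "EncounterEvent",
    "EncounterCorpus",
    "FrequencyTable",
    "ParetoCurve",
    "CorpusSummary",
    "ColumnMap",
    "ConfigurationError",
    "read_events",
    "write_events",
    "filter_section",
    "stratify_by_practice",
    "build_frequency_table",
    "type_token_ratio",
    "usage_depth_profile",
    "pareto_curve",
    "summarize",
]


class ConfigurationError(ValueError):
    """Raised for unusable column mappings or analysis options."""


@dataclass(frozen=True, slots=True)
class EncounterEvent:
    patient_id: str
    practice_id: str
    date: pd.Timestamp
    code: ClinicalCode


@dataclass(frozen=True)
class ColumnMap:
    """Names of the required columns in a delimited event extract."""

    patient: str = "patient_id"
    practice: str = "practice_id"
    date: str = "date"
    code: str = "code"


@dataclass(frozen=True)
class EncounterCorpus:
    """An ordered collection of coded events.

    Events are held column-wise in a DataFrame (``patient_id``,
    ``practice_id``, ``date``, ``code``) for speed at corpus scale; the
    ``events`` iterator materialises :class:`EncounterEvent` objects on
    demand.  ``rejects`` carries the rows dropped during ingestion
    (line_number, raw_code, reason), empty for programmatically built
    corpora.
    """

    df: pd.DataFrame
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["line_number", "raw_code", "reason"])
    )

    @property
    def n_tokens(self) -> int:
        return len(self.df)

    @property
    def n_types(self) -> int:
        return int(self.df["code"].nunique())

    def events(self) -> Iterator[EncounterEvent]:
        for row in self.df.itertuples(index=False):
            yield EncounterEvent(
                row.patient_id, row.practice_id, row.date, ClinicalCode(row.code)
            )

    def codes(self) -> dict[str, ClinicalCode]:
        """Map from code text to parsed code for every distinct code used."""
        return {t: ClinicalCode(t) for t in self.df["code"].unique()}

    @staticmethod
    def from_events(events) -> "EncounterCorpus":
        rows = [
            (e.patient_id, e.practice_id, e.date, e.code.text) for e in events
        ]
        df = pd.DataFrame(rows, columns=["patient_id", "practice_id", "date", "code"])
        return EncounterCorpus(df)


def read_events(
    source: str | Path | io.TextIOBase,
    columns: ColumnMap | Mapping[str, str] | None = None,
    sep: str | None = None,
) -> EncounterCorpus:
    """Read a delimited event extract into a corpus.

    ``source`` may be a path (gzip handled transparently by pandas) or an
    open text stream.  The file must have a header row; ``columns`` maps
    the logical fields to the actual column names.  The delimiter is
    sniffed from the header unless given.

    Rows whose code fails validation are collected into the corpus's
    ``rejects`` frame with their 1-based data line number and the reason;
    if more than half of all rows are rejected a
    :class:`ConfigurationError` is raised, since that almost always means
    the column mapping is wrong rather than the data dirty.
    """
    if columns is None:
        columns = ColumnMap()
    elif isinstance(columns, Mapping):
        columns = ColumnMap(**columns)

    df = pd.read_csv(source, sep=sep, engine="python", dtype=str, keep_default_na=False)
    missing = [
        c for c in (columns.patient, columns.practice, columns.date, columns.code)
        if c not in df.columns
    ]
    if missing:
        raise ConfigurationError(
            f"required column(s) {missing} not found; file has {list(df.columns)}"
        )
    df = df.rename(
        columns={
            columns.patient: "patient_id",
            columns.practice: "practice_id",
            columns.date: "date",
            columns.code: "code",
        }
    )[["patient_id", "practice_id", "date", "code"]]

    normalised = []
    reject_rows = []
    for i, raw in enumerate(df["code"].tolist(), start=1):
        try:
            normalised.append(parse_code(raw).text)
        except MalformedCodeError as exc:
            normalised.append(None)
            reject_rows.append((i, raw, str(exc)))
    df["code"] = normalised
    rejects = pd.DataFrame(reject_rows, columns=["line_number", "raw_code", "reason"])
    if len(df) > 0 and len(rejects) > len(df) / 2:
        raise ConfigurationError(
            f"{len(rejects)} of {len(df)} rows rejected; check the column mapping"
        )
    kept = df[df["code"].notna()].reset_index(drop=True)
    kept["date"] = pd.to_datetime(kept["date"], errors="coerce")
    return EncounterCorpus(kept, rejects)


def write_events(corpus: EncounterCorpus, path: str | Path, sep: str = ",") -> None:
    """Write a corpus back out in the same four-column delimited format."""
    out = corpus.df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep=sep, index=False)


def write_rejects(corpus: EncounterCorpus, path: str | Path) -> None:
    corpus.rejects.to_csv(path, sep="\t", index=False)


def filter_section(corpus: EncounterCorpus, section: Section) -> EncounterCorpus:
    """Events whose code belongs to the given section, in stable order."""
    first = corpus.df["code"].str[0]
    if section is Section.PROCESS_OF_CARE:
        mask = first.str.isdigit()
    elif section is Section.DIAGNOSIS:
        mask = first.str.isupper() & ~first.str.isdigit()
    else:
        mask = first.str.islower()
    return EncounterCorpus(corpus.df[mask].reset_index(drop=True))


def stratify_by_practice(corpus: EncounterCorpus) -> dict[str, EncounterCorpus]:
    """Split the corpus by practice identifier; strata partition the events."""
    return {
        pid: EncounterCorpus(g.reset_index(drop=True))
        for pid, g in corpus.df.groupby("practice_id", sort=True)
    }


@dataclass(frozen=True)
class FrequencyTable:
    """Per-code usage counts and derived views.

    ``rank_frequency`` is the Zipf view: rank r (from 1) against count
    f(r), sorted by descending count with ties broken by code text.
    ``freq_sample`` is the frequency-of-frequencies view — one observation
    per distinct code, namely its count — and is the sample on which the
    power law P(f) ~ f^(-beta) is fitted.
    """

    counts: pd.Series  # index: code text, values: counts, sorted desc

    def __post_init__(self) -> None:
        if len(self.counts) == 0:
            raise EmptyInputError("frequency table is empty")

    @property
    def n_tokens(self) -> int:
        return int(self.counts.sum())

    @property
    def n_types(self) -> int:
        return len(self.counts)

    @property
    def rank_frequency(self) -> np.ndarray:
        """Array of shape (n_types, 2): rank, f(rank)."""
        f = self.counts.to_numpy()
        return np.column_stack([np.arange(1, len(f) + 1), f])

    @property
    def freq_sample(self) -> np.ndarray:
        """Multiset of counts, one per distinct code (unsorted semantics)."""
        return self.counts.to_numpy().copy()

    def code_objects(self) -> dict[str, ClinicalCode]:
        return {t: ClinicalCode(t) for t in self.counts.index}


def build_frequency_table(corpus: EncounterCorpus) -> FrequencyTable:
    """Count code usage and build the rank/frequency views."""
    if corpus.n_tokens == 0:
        raise EmptyInputError("corpus has no events")
    counts = corpus.df["code"].value_counts()
    # deterministic rank order: count desc, then code text asc
    counts = counts.sort_index().sort_values(ascending=False, kind="stable")
    return FrequencyTable(counts)


def type_token_ratio(table: FrequencyTable) -> float:
    """TTR as a percentage: 100 * types / tokens.

    A low TTR signals heavy repetition of a small vocabulary; a high TTR a
    rich vocabulary relative to corpus size.
    """
    return 100.0 * table.n_types / table.n_tokens


def usage_depth_profile(table: FrequencyTable, weighting: str = "by_type") -> DepthProfile:
    """Depth distribution of the codes actually *used* in a corpus.

    ``by_type`` weights each distinct code once (the default: the question
    is which levels of the hierarchy the vocabulary draws on); ``by_token``
    weights each code by its usage count.
    """
    if weighting not in ("by_type", "by_token"):
        raise ConfigurationError(f"weighting must be by_type or by_token, got {weighting!r}")
    depths = [len(t) for t in table.counts.index]
    weights = None if weighting == "by_type" else table.counts.to_numpy(dtype=float)
    return _profile(f"usage[{weighting}]", depths, weights)


@dataclass(frozen=True)
class ParetoCurve:
    """Empirical tail CDF of the frequency-of-frequencies sample:
    points (x, P(X >= x)) over every distinct observed count, ascending in
    x.  This is the curve the log-log Pareto plots display."""

    x: np.ndarray
    tail_prob: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.x, self.tail_prob])


def pareto_curve(table: FrequencyTable) -> ParetoCurve:
    """Empirical P(X >= x) over the distinct observed frequencies."""
    sample = table.freq_sample
    xs = np.unique(sample)  # ascending
    n = sample.size
    # count of observations >= x for each distinct x
    sorted_sample = np.sort(sample)
    ge = n - np.searchsorted(sorted_sample, xs, side="left")
    return ParetoCurve(xs.astype(int), ge / n)


@dataclass(frozen=True)
class CorpusSummary:
    ttr_percent: float
    n_tokens: int
    n_types: int
    mean_code_depth: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize(corpus: EncounterCorpus) -> CorpusSummary:
    """TTR, sizes and mean depth of the codes used (type-weighted)."""
    table = build_frequency_table(corpus)
    depths = np.array([len(t) for t in table.counts.index])
    return CorpusSummary(
        ttr_percent=type_token_ratio(table),
        n_tokens=table.n_tokens,
        n_types=table.n_types,
        mean_code_depth=float(depths.mean()),
    )
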