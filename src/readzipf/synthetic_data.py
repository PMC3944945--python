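"""Synthetic coded-event corpora with controlled statistical structure.

Real primary-care coding extracts cannot be redistributed, so every stage
of the pipeline is exercised on generated corpora that emulate the
statistical features the analysis targets:

* a hierarchical terminology with section-dependent depth ceilings
  (medication stops at depth 4, diagnosis/procedure reach 5);
* Zipfian code usage, f(r) proportional to r^(-alpha), sampled as an
  i.i.d. token stream so that the fitted frequency-distribution exponent
  recovers beta = 1 + 1/alpha;
* a tunable depth-rank correlation (common codes shallower), the
  mechanism behind the core/peripheral depth difference;
* an optional injected block of very-high-frequency codes that rise above
  the power law — a synthetic core vocabulary;
* per-practice panels sweeping alpha and vocabulary size, spanning
  realistic per-practice exponent (beta roughly 1.5-2.1) and type-token
  ratio (a fraction of a percent up to ~11%) ranges;
* an "indexical" regime in which every code sits at one fixed depth and
  counts follow a narrow shifted-Poisson law — deliberately *not* a power
  law, mirroring how medication data behave.

Every corpus is emitted together with a :class:`GroundTruth` sidecar
recording the configuration and the realised per-code counts, so tests
can validate any pipeline output by independent recount.  All randomness
flows from the config seed; identical seeds give byte-identical corpora.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coding_model import ClinicalCode, EmptyInputError, MAX_DEPTH, Section, Terminology
from .corpus_stats import ConfigurationError, EncounterCorpus, write_events

__all__ = [
    "SyntheticConfig",
    "SectionSpec",
    "GroundTruth",
    "generate_terminology",
    "sample_zipf_corpus",
    "sample_indexical_corpus",
    "generate_practice_panel",
    "write_corpus_with_truth",
]

_INITIALS = {
    Section.PROCESS_OF_CARE: "0123456789",
    Section.DIAGNOSIS: "ABCDEFGHIJKLMNOPQRSTUVWXYZ",
    Section.MEDICATION: "abcdefghijklmnopqrstuvwxyz",
}
_ALPHABET = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"
_EPOCH = np.datetime64("2003-01-01")
_N_DAYS = 2557  # 2003-01-01 .. 2009-12-31


@dataclass(frozen=True)
class SectionSpec:
    size: int
    depth_ceiling: int = MAX_DEPTH


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic corpus (typically one practice).

    ``alpha`` is the Zipf rank-frequency exponent; the implied
    frequency-distribution exponent is beta = 1 + 1/alpha, so alpha in
    roughly [0.9, 2.0] spans the realistic beta range 1.5-2.1.
    ``depth_rank_correlation`` in [-1, 1] controls how strongly common
    (low-rank) codes prefer shallow depths: with probability |rho| a
    code's depth follows the monotone map from rank quantile to the depth
    quantile of the selected codes (reversed when rho < 0), otherwise the
    code is drawn at random, so rho=0 makes depth independent of rank.  ``core_size`` > 0 flattens the head
    into a synthetic core vocabulary: the top ``core_size`` ranks each get
    ``core_boost`` times the weight the Zipf line assigns to rank
    core_size+1, a high-frequency plateau rising above the power law,
    while lower ranks continue the Zipf law unchanged.  For the ``indexical`` generator all codes sit at
    ``depth_ceiling`` and per-code counts are 1 + Poisson(poisson_mean).
    """

    n_types: int = 5000
    n_tokens: int = 200_000
    alpha: float = 1.5
    section: Section = Section.DIAGNOSIS
    depth_rank_correlation: float = 0.5
    depth_ceiling: int = MAX_DEPTH
    seed: int = 0
    generator: str = "zipfian"  # or "indexical"
    practice_id: str = "P001"
    poisson_mean: float = 9.0
    core_size: int = 0
    core_boost: float = 3.0

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise ConfigurationError("n_types must be >= 2")
        if self.generator not in ("zipfian", "indexical"):
            raise ConfigurationError(f"unknown generator {self.generator!r}")
        if self.generator == "zipfian" and 0 < self.n_tokens < self.n_types:
            raise ConfigurationError("zipfian corpora need n_tokens >= n_types")
        if self.depth_ceiling > MAX_DEPTH:
            raise ConfigurationError(f"depth_ceiling exceeds {MAX_DEPTH}")
        if not -1.0 <= self.depth_rank_correlation <= 1.0:
            raise ConfigurationError("depth_rank_correlation must lie in [-1, 1]")
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Exact description of an emitted corpus: the generating config plus
    the realised per-code counts, depths and section labels (and, for
    panels, the per-practice token totals).  ``injected`` lists the code
    texts of any synthetic core block."""

    config: SyntheticConfig | None
    counts: Mapping[str, int]
    depths: Mapping[str, int]
    sections: Mapping[str, str]
    practice_sizes: Mapping[str, int]
    injected: tuple[str, ...] = ()
    members: tuple["GroundTruth", ...] = ()

    @property
    def n_tokens(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def n_types_used(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)

    def as_dict(self) -> dict:
        cfg = None
        if self.config is not None:
            cfg = dataclasses.asdict(self.config)
            cfg["section"] = self.config.section.value
        return {
            "config": cfg,
            "counts": dict(self.counts),
            "depths": dict(self.depths),
            "sections": dict(self.sections),
            "practice_sizes": dict(self.practice_sizes),
            "injected": list(self.injected),
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), sort_keys=True)


def generate_terminology(
    seed: int, sections: Mapping[Section, SectionSpec]
) -> Terminology:
    """Grow a prefix-closed random terminology.

    Each section starts from a handful of depth-1 roots with
    section-appropriate initial characters; children are formed by
    appending one alphanumeric character to an existing code, never
    exceeding the section's depth ceiling.  Growth prefers deeper parents,
    so a reasonable share of codes reaches the ceiling.  Deterministic in
    the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    all_codes: set[str] = set()
    ceilings: dict[Section, int] = {}
    for section in sorted(sections, key=lambda s: s.value):
        spec = sections[section]
        if spec.depth_ceiling > MAX_DEPTH:
            raise ConfigurationError(
                f"depth ceiling {spec.depth_ceiling} for {section} exceeds {MAX_DEPTH}"
            )
        if spec.size < 1:
            raise ConfigurationError("section size must be >= 1")
        ceilings[section] = spec.depth_ceiling
        initials = list(_INITIALS[section])
        rng.shuffle(initials)
        n_roots = min(len(initials), max(2, spec.size // 150 + 2))
        n_roots = min(n_roots, spec.size)
        codes = [initials[i] for i in range(n_roots)]
        # parents still open for children: (text, n_children)
        open_parents: list[str] = [c for c in codes if len(c) < spec.depth_ceiling]
        n_children: dict[str, int] = {}
        taken = set(codes)
        while len(codes) < spec.size:
            if not open_parents:
                raise ConfigurationError(
                    f"cannot grow section {section} to {spec.size} codes under its ceiling"
                )
            weights = np.array([len(p) ** 2 for p in open_parents], dtype=float)
            idx = rng.choice(len(open_parents), p=weights / weights.sum())
            parent = open_parents[idx]
            child = None
            for _ in range(8):
                cand = parent + _ALPHABET[rng.integers(0, len(_ALPHABET))]
                if cand not in taken:
                    child = cand
                    break
            if child is None:
                remaining = [parent + ch for ch in _ALPHABET if parent + ch not in taken]
                if not remaining:
                    open_parents.pop(idx)
                    continue
                child = remaining[rng.integers(0, len(remaining))]
            taken.add(child)
            codes.append(child)
            n_children[parent] = n_children.get(parent, 0) + 1
            if n_children[parent] >= len(_ALPHABET):
                open_parents.pop(idx)
            if len(child) < spec.depth_ceiling:
                open_parents.append(child)
        all_codes.update(codes)
    return Terminology(
        frozenset(ClinicalCode(t) for t in all_codes), ceilings
    )


def _bind_codes_to_ranks(
    rng: np.random.Generator,
    pool: Sequence[ClinicalCode],
    n: int,
    rho: float,
    depth_ceiling: int,
) -> np.ndarray:
    """Choose n codes and bind them to ranks 1..n under the depth model.

    A rank is "monotone" with probability |rho|: monotone ranks receive
    the selected codes in order of increasing depth (decreasing for
    rho < 0), i.e. the rank quantile is mapped onto the empirical depth
    quantile of the selection, so common codes come out shallower.  The
    remaining ranks receive codes at random, so rho = 0 makes depth
    independent of rank.  Works for any depth marginal the terminology
    happens to offer.
    """
    eligible = [c.text for c in pool if c.depth <= depth_ceiling]
    if len(eligible) < n:
        raise ConfigurationError(
            f"terminology offers {len(eligible)} codes at depth <= {depth_ceiling}, need {n}"
        )
    sel = rng.choice(len(eligible), size=n, replace=False)
    texts = np.array(eligible, dtype=object)[sel]
    depths = np.array([len(t) for t in texts])
    mono_ranks = np.flatnonzero(rng.random(n) < abs(rho))
    other_ranks = np.setdiff1d(np.arange(n), mono_ranks, assume_unique=True)
    perm = rng.permutation(n)  # which codes go to the monotone slots
    mono_codes = perm[: mono_ranks.size]
    other_codes = perm[mono_ranks.size:]
    # random tie-break among equal depths, then sort monotone codes by depth
    order = np.argsort(depths[mono_codes], kind="stable")
    if rho < 0:
        order = order[::-1]
    out = np.empty(n, dtype=object)
    out[mono_ranks] = texts[mono_codes[order]]
    out[other_ranks] = texts[rng.permutation(other_codes)]
    return out.astype(str)


def _events_frame(
    rng: np.random.Generator, code_per_token: np.ndarray, practice_id: str
) -> pd.DataFrame:
    n = code_per_token.size
    n_patients = max(1, n // 20)
    patients = rng.integers(0, n_patients, size=n)
    days = rng.integers(0, _N_DAYS, size=n)
    return pd.DataFrame(
        {
            "patient_id": [f"S{p:06d}" for p in patients],
            "practice_id": practice_id,
            "date": _EPOCH + days.astype("timedelta64[D]"),
            "code": code_per_token,
        }
    )


def sample_zipf_corpus(
    term: Terminology, config: SyntheticConfig
) -> tuple[EncounterCorpus, GroundTruth]:
    """Draw an i.i.d. Zipfian token stream over codes from one section.

    Ranks 1..n_types get sampling probability proportional to r^(-alpha);
    each rank is bound to a terminology code whose depth follows the
    depth-rank mixture model.  If ``core_size`` > 0 the head is flattened
    into an injected high-frequency plateau (see
    :class:`SyntheticConfig`); the injected code texts are recorded in
    the ground truth.
    """
    if config.n_tokens <= 0:
        raise EmptyInputError("n_tokens must be positive; refusing to emit an empty corpus")
    pool = term.in_section(config.section)
    if len(pool) < config.n_types:
        raise ConfigurationError(
            f"terminology offers {len(pool)} codes in {config.section}, need {config.n_types}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_types
    n_core = config.core_size
    if n_core >= n:
        raise ConfigurationError("core_size must be smaller than n_types")
    # tail ranks continue the Zipf law at r = n_core+1..n; the injected block
    # replaces the head by a flat plateau core_boost times above the line
    zipf_w = np.arange(n_core + 1, n + 1, dtype=float) ** (-config.alpha)
    weights = np.concatenate([np.full(n_core, config.core_boost * zipf_w[0]), zipf_w])
    probs = weights / weights.sum()

    texts = _bind_codes_to_ranks(
        rng, pool, n, config.depth_rank_correlation, config.depth_ceiling
    )

    draws = rng.choice(n, size=config.n_tokens, p=probs)
    counts = np.bincount(draws, minlength=n)
    df = _events_frame(rng, texts[draws], config.practice_id)
    truth = GroundTruth(
        config=config,
        counts={t: int(c) for t, c in zip(texts, counts)},
        depths={t: len(t) for t in texts},
        sections={t: ClinicalCode(t).section.value for t in texts},
        practice_sizes={config.practice_id: int(config.n_tokens)},
        injected=tuple(texts[:n_core]),
    )
    return EncounterCorpus(df), truth


def sample_indexical_corpus(
    term: Terminology, config: SyntheticConfig
) -> tuple[EncounterCorpus, GroundTruth]:
    """Draw a corpus in which every code sits at the section's depth
    ceiling and per-code counts are 1 + Poisson(poisson_mean) — a narrow,
    non-heavy-tailed usage law (the medication-like indexical regime).
    The realised token total is the sum of the drawn counts."""
    pool = [c for c in term.in_section(config.section) if c.depth == config.depth_ceiling]
    if len(pool) < config.n_types:
        raise ConfigurationError(
            f"terminology offers {len(pool)} depth-{config.depth_ceiling} codes in "
            f"{config.section}, need {config.n_types}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    texts = np.array(sorted(c.text for c in pool))
    idx = rng.choice(len(texts), size=config.n_types, replace=False)
    texts = texts[np.sort(idx)]
    counts = 1 + rng.poisson(config.poisson_mean, size=config.n_types)
    stream = np.repeat(np.arange(config.n_types), counts)
    rng.shuffle(stream)
    df = _events_frame(rng, texts[stream], config.practice_id)
    truth = GroundTruth(
        config=config,
        counts={t: int(c) for t, c in zip(texts, counts)},
        depths={t: len(t) for t in texts},
        sections={t: ClinicalCode(t).section.value for t in texts},
        practice_sizes={config.practice_id: int(counts.sum())},
    )
    return EncounterCorpus(df), truth


def _generate_one(term: Terminology, config: SyntheticConfig):
    if config.generator == "indexical":
        return sample_indexical_corpus(term, config)
    return sample_zipf_corpus(term, config)


def generate_practice_panel(
    configs: Sequence[SyntheticConfig], term: Terminology | None = None
) -> tuple[EncounterCorpus, GroundTruth]:
    """Concatenate per-practice corpora into one multi-practice panel.

    Practice ids must be distinct; stratifying the result by practice
    recovers each member corpus exactly.  If no terminology is supplied
    one is grown (seeded from the first config) large enough for every
    member."""
    if not configs:
        raise ConfigurationError("need at least one practice config")
    ids = [c.practice_id for c in configs]
    if len(set(ids)) != len(ids):
        raise ConfigurationError(f"duplicate practice ids in panel: {ids}")
    if term is None:
        need: dict[Section, int] = {}
        ceil: dict[Section, int] = {}
        for c in configs:
            need[c.section] = max(need.get(c.section, 0), c.n_types)
            ceil[c.section] = max(ceil.get(c.section, 1), c.depth_ceiling)
        term = generate_terminology(
            configs[0].seed,
            {s: SectionSpec(size=int(need[s] * 2.5) + 50, depth_ceiling=ceil[s]) for s in need},
        )
    frames = []
    truths = []
    for cfg in configs:
        corpus, truth = _generate_one(term, cfg)
        frames.append(corpus.df)
        truths.append(truth)
    df = pd.concat(frames, ignore_index=True)
    counts: dict[str, int] = {}
    depths: dict[str, int] = {}
    secs: dict[str, str] = {}
    sizes: dict[str, int] = {}
    injected: list[str] = []
    for t in truths:
        for k, v in t.counts.items():
            counts[k] = counts.get(k, 0) + v
        depths.update(t.depths)
        secs.update(t.sections)
        sizes.update(t.practice_sizes)
        injected.extend(t.injected)
    truth = GroundTruth(
        config=None,
        counts=counts,
        depths=depths,
        sections=secs,
        practice_sizes=sizes,
        injected=tuple(injected),
        members=tuple(truths),
    )
    return EncounterCorpus(df), truth


def write_corpus_with_truth(
    corpus: EncounterCorpus, truth: GroundTruth, events_path: str | Path
) -> Path:
    """Write the event file plus a `.truth.json` ground-truth sidecar;
    returns the sidecar path."""
    events_path = Path(events_path)
    write_events(corpus, events_path)
    sidecar = events_path.with_suffix(events_path.suffix + ".truth.json")
    sidecar.write_text(truth.to_json() + "\n", encoding="utf-8")
    return sidecar
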