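"""Core/peripheral vocabulary segmentation of a fitted frequency distribution.

On the log-log Pareto plot of many clinical-coding corpora two regimes are
visible: a power-law region of rare codes (the *peripheral vocabulary*)
and, at high frequency, a region that rises above the fitted line — a
small set of workhorse codes used far more often than the power law
extrapolates (the *core vocabulary*).  The transition frequency f* is
located where the empirical tail curve starts to exceed the fitted model
line and keeps exceeding it out to the largest observed frequency.

In the rank-frequency view the core regime is a *flattening* of the head:
the most common codes have more similar frequencies than the Zipf line
extrapolated from the rare codes predicts.  On the Pareto (tail-CDF) plot
this appears as the empirical curve dropping *below* the fitted line at
high frequency — there are fewer very-high-frequency codes than the power
law extrapolates.  The deviation is therefore measured as the signed
deficit in log10 tail-probability space, log10 P(x) - log10 S(x) >
epsilon, required to persist out to the largest observed frequency.  The
signed test keeps symmetric small-sample noise in the extreme upper tail
from triggering a spurious split; for the same reason a detected core
must contain at least ``min_core_size`` distinct codes — a "core" of one
or two extreme order statistics is indistinguishable from noise.  Both
knobs are exposed as configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .coding_model import ClinicalCode
from .corpus_stats import ConfigurationError, FrequencyTable, pareto_curve
from .powerlaw_fit import PowerLawFit, model_tail

__all__ = [
    "VocabularyPartition",
    "partition_vocabulary",
    "region_mean_depths",
    "DEFAULT_EPSILON",
    "DEFAULT_MIN_CORE_SIZE",
]

DEFAULT_EPSILON = 0.05
DEFAULT_MIN_CORE_SIZE = 10


@dataclass(frozen=True)
class VocabularyPartition:
    """Core/peripheral split of a corpus vocabulary.

    ``core_codes`` hold every code with count >= ``transition_frequency``;
    ``peripheral_codes`` the rest.  A *degenerate* partition means no
    persistent deviation from the fitted power law was found: the whole
    vocabulary is peripheral and the core statistics are absent.
    """

    transition_frequency: int | None
    core_codes: frozenset[str]
    peripheral_codes: frozenset[str]
    epsilon: float
    degenerate: bool
    mean_depth_core: float | None = None
    mean_depth_peripheral: float | None = None

    @property
    def n_core(self) -> int:
        return len(self.core_codes)

    @property
    def n_peripheral(self) -> int:
        return len(self.peripheral_codes)

    def as_dict(self) -> dict:
        return {
            "transition_frequency": self.transition_frequency,
            "n_core": self.n_core,
            "n_peripheral": self.n_peripheral,
            "mean_depth_core": self.mean_depth_core,
            "mean_depth_peripheral": self.mean_depth_peripheral,
            "degenerate": self.degenerate,
            "epsilon": self.epsilon,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict())


def partition_vocabulary(
    table: FrequencyTable,
    fit: PowerLawFit,
    epsilon: float = DEFAULT_EPSILON,
    min_core_size: int = DEFAULT_MIN_CORE_SIZE,
) -> VocabularyPartition:
    """Locate the core/peripheral transition frequency.

    f* is the smallest observed frequency x > xmin at which
    ``log10 P(x) - log10 S(x) > epsilon`` holds and keeps holding for
    every larger observed frequency, where S is the empirical tail CDF
    over the whole vocabulary and P the fitted model tail scaled by the
    tail fraction n_tail/n_types (so the two curves coincide at xmin).
    Codes with count >= f* form the core.  If no such x exists, or the
    would-be core has fewer than ``min_core_size`` codes, the partition is
    degenerate.
    """
    if epsilon <= 0:
        raise ConfigurationError(f"epsilon must be > 0, got {epsilon}")
    curve = pareto_curve(table)
    xs = curve.x
    S = curve.tail_prob
    scale = fit.n_tail / table.n_types
    above = xs > fit.xmin
    if not above.any() or not np.isfinite(epsilon):
        return _degenerate(table, epsilon)
    x_above = xs[above]
    deficit = np.log10(scale * model_tail(x_above, fit.xmin, fit.beta)) - np.log10(S[above])
    exceed = deficit > epsilon
    # persistent from x onward <=> suffix-AND of the exceedance flags
    persistent = np.minimum.accumulate(exceed[::-1])[::-1]
    if not persistent.any():
        return _degenerate(table, epsilon)
    f_star = int(x_above[np.argmax(persistent)])
    counts = table.counts
    core = frozenset(counts.index[counts >= f_star])
    if len(core) < min_core_size:
        return _degenerate(table, epsilon)
    peripheral = frozenset(counts.index[counts < f_star])
    return VocabularyPartition(
        transition_frequency=f_star,
        core_codes=core,
        peripheral_codes=peripheral,
        epsilon=epsilon,
        degenerate=False,
    )


def _degenerate(table: FrequencyTable, epsilon: float) -> VocabularyPartition:
    return VocabularyPartition(
        transition_frequency=None,
        core_codes=frozenset(),
        peripheral_codes=frozenset(table.counts.index),
        epsilon=epsilon,
        degenerate=True,
    )


def region_mean_depths(
    partition: VocabularyPartition,
    codes: Mapping[str, ClinicalCode],
    weighting: str = "by_type",
    counts: Mapping[str, int] | None = None,
) -> tuple[float | None, float | None]:
    """Mean code depth in the core and peripheral regions.

    ``by_type`` (default) averages each distinct code once — the regions
    are sets of vocabulary items; ``by_token`` weights each code by its
    usage count, which then must be supplied.  For a degenerate partition
    the core mean is None and the peripheral mean still returned.
    """
    if weighting not in ("by_type", "by_token"):
        raise ConfigurationError(f"weighting must be by_type or by_token, got {weighting!r}")
    if weighting == "by_token" and counts is None:
        raise ConfigurationError("by_token weighting requires per-code counts")

    def mean_depth(region: frozenset[str]) -> float | None:
        if not region:
            return None
        depths = np.array([codes[t].depth for t in sorted(region)], dtype=float)
        if weighting == "by_type":
            return float(depths.mean())
        w = np.array([counts[t] for t in sorted(region)], dtype=float)
        return float((depths * w).sum() / w.sum())

    return mean_depth(partition.core_codes), mean_depth(partition.peripheral_codes)


def partition_with_depths(
    table: FrequencyTable,
    fit: PowerLawFit,
    epsilon: float = DEFAULT_EPSILON,
    min_core_size: int = DEFAULT_MIN_CORE_SIZE,
    weighting: str = "by_type",
) -> VocabularyPartition:
    """Partition and attach region mean depths in one call."""
    part = partition_vocabulary(table, fit, epsilon=epsilon, min_core_size=min_core_size)
    core_d, peri_d = region_mean_depths(
        part, table.code_objects(), weighting=weighting,
        counts=table.counts.to_dict() if weighting == "by_token" else None,
    )
    return replace(part, mean_depth_core=core_d, mean_depth_peripheral=peri_d)
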