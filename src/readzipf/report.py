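"""End-to-end analysis orchestration and report serialisation.

``run_analysis`` ties the stages together the way the study workflow
does: ingest (or simulate) a coded-event corpus, split it by section,
fit the discrete power law to each section's frequency sample, test
plausibility by bootstrap, segment core/peripheral vocabulary, profile
code depths, and optionally repeat the fit per practice.  Results land
in a JSON report plus TSV tables and log-log Pareto plots.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import __version__
from .coding_model import Section
from .corpus_stats import (
    ColumnMap,
    ConfigurationError,
    EncounterCorpus,
    build_frequency_table,
    filter_section,
    pareto_curve,
    read_events,
    stratify_by_practice,
    summarize,
    usage_depth_profile,
)
from .powerlaw_fit import (
    DEFAULT_BETA_MAX,
    DEFAULT_MIN_TAIL,
    PowerLawFit,
    fit_power_law,
    goodness_of_fit,
    model_tail,
)
from .synthetic_data import SyntheticConfig, generate_practice_panel
from .vocabulary_structure import DEFAULT_EPSILON, partition_with_depths

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis", "validate_report"]

_SECTION_BY_NAME = {s.value: s for s in Section}


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one pipeline run (mirrors the YAML/JSON config)."""

    input_path: str | None = None
    columns: ColumnMap = field(default_factory=ColumnMap)
    sep: str | None = None
    simulate: tuple[SyntheticConfig, ...] = ()
    sections_to_analyze: tuple[str, ...] = ("diagnosis", "process_of_care", "medication")
    per_practice: bool = False
    per_practice_section: str = "diagnosis"
    xmin_strategy: str = "scan"
    min_tail: int = DEFAULT_MIN_TAIL
    beta_max: float = DEFAULT_BETA_MAX
    n_boot: int = 0  # 0 disables the bootstrap p-value
    seed: int = 0
    epsilon: float = DEFAULT_EPSILON
    output_dir: str | None = None
    plots: bool = True

    @staticmethod
    def from_mapping(raw: Mapping[str, Any]) -> "AnalysisConfig":
        raw = dict(raw)
        inp = raw.get("input", {}) or {}
        fit = raw.get("fit", {}) or {}
        part = raw.get("partition", {}) or {}
        sim = []
        for entry in raw.get("simulate", []) or []:
            entry = dict(entry)
            if "section" in entry:
                entry["section"] = _SECTION_BY_NAME[entry["section"]]
            sim.append(SyntheticConfig(**entry))
        cols = inp.get("columns")
        return AnalysisConfig(
            input_path=inp.get("events"),
            columns=ColumnMap(**cols) if cols else ColumnMap(),
            sep=inp.get("sep"),
            simulate=tuple(sim),
            sections_to_analyze=tuple(
                raw.get("sections_to_analyze", ("diagnosis", "process_of_care", "medication"))
            ),
            per_practice=bool(raw.get("per_practice", False)),
            per_practice_section=raw.get("per_practice_section", "diagnosis"),
            xmin_strategy=fit.get("xmin_strategy", "scan"),
            min_tail=int(fit.get("min_tail", DEFAULT_MIN_TAIL)),
            beta_max=float(fit.get("beta_max", DEFAULT_BETA_MAX)),
            n_boot=int(fit.get("n_boot", 0)),
            seed=int(fit.get("seed", 0)),
            epsilon=float(part.get("epsilon", DEFAULT_EPSILON)),
            output_dir=raw.get("output_dir"),
            plots=bool(raw.get("plots", True)),
        )


@dataclass(frozen=True)
class AnalysisReport:
    sections: dict
    practices: dict
    provenance: dict

    def as_dict(self) -> dict:
        return {
            "sections": self.sections,
            "practices": self.practices,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), sort_keys=True, indent=2)


#: Minimal structural schema for the JSON report (checked by validate_report).
REPORT_SCHEMA = {
    "type": "object",
    "required": ["sections", "practices", "provenance"],
    "provenance_required": ["input", "config", "seed", "version"],
    "section_required": ["summary", "fit", "partition", "depth_profile"],
}


def validate_report(doc: Mapping[str, Any]) -> None:
    """Raise ValueError if the report does not follow REPORT_SCHEMA."""
    for key in REPORT_SCHEMA["required"]:
        if key not in doc:
            raise ValueError(f"report missing top-level key {key!r}")
    for key in REPORT_SCHEMA["provenance_required"]:
        if key not in doc["provenance"]:
            raise ValueError(f"report provenance missing {key!r}")
    for name, block in doc["sections"].items():
        if "error" in block:
            continue
        for key in REPORT_SCHEMA["section_required"]:
            if key not in block:
                raise ValueError(f"section {name!r} missing {key!r}")
        fit = block["fit"]
        if fit is not None:
            if abs(fit["beta"] - (1 + fit["k"])) > 1e-12 or abs(fit["alpha"] - 1 / fit["k"]) > 1e-9:
                raise ValueError(f"section {name!r} fit violates the exponent identity")


def _analyse_block(
    corpus: EncounterCorpus, cfg: AnalysisConfig, gof_seed: int
) -> dict:
    table = build_frequency_table(corpus)
    summary = summarize(corpus)
    block: dict[str, Any] = {"summary": summary.as_dict()}
    try:
        fit = fit_power_law(
            table.freq_sample,
            xmin_strategy=cfg.xmin_strategy,
            beta_max=cfg.beta_max,
            min_tail=cfg.min_tail,
        )
        if cfg.n_boot:
            p = goodness_of_fit(
                table.freq_sample, fit, n_boot=cfg.n_boot, seed=gof_seed,
                beta_max=cfg.beta_max, min_tail=cfg.min_tail,
            )
            fit = dataclasses.replace(fit, p_value=p, n_boot=cfg.n_boot, seed=gof_seed)
        block["fit"] = fit.as_dict()
        part = partition_with_depths(table, fit, epsilon=cfg.epsilon)
        block["partition"] = part.as_dict()
    except Exception as exc:  # per-stratum failures are recorded, not fatal
        block.setdefault("fit", None)
        block.setdefault("partition", None)
        block["fit_error"] = f"{type(exc).__name__}: {exc}"
        fit = None
    block["depth_profile"] = {
        w: usage_depth_profile(table, w).as_dict() for w in ("by_type", "by_token")
    }
    block["pareto"] = pareto_curve(table).as_array().tolist()
    return block


def _plot_block(block: dict, title: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = np.asarray(block["pareto"])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.loglog(pts[:, 0], pts[:, 1], "o", ms=3, mfc="none", label="empirical")
    fit = block.get("fit")
    if fit:
        xs = np.unique(np.geomspace(fit["xmin"], pts[:, 0].max(), 200).round()).astype(float)
        scale = fit["n_tail"] / block["summary"]["n_types"]
        ax.loglog(xs, scale * model_tail(xs, fit["xmin"], fit["beta"]), ":",
                  label=f"power law, $\\beta$={fit['beta']:.2f}")
        ttr = block["summary"]["ttr_percent"]
        ax.set_title(f"{title}  ($\\beta$={fit['beta']:.2f}, TTR={ttr:.2f}%)")
    else:
        ax.set_title(title)
    ax.set_xlabel("frequency $x$")
    ax.set_ylabel("$P(X \\geq x)$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_analysis(cfg: AnalysisConfig) -> AnalysisReport:
    """Execute the full pipeline described by ``cfg``.

    Returns the report; when ``cfg.output_dir`` is set, also writes
    report.json, freq_table.tsv, pareto_points.tsv, depth_profile.tsv and
    (unless disabled) plots/*.png.
    """
    if cfg.input_path is not None:
        corpus = read_events(cfg.input_path, cfg.columns, sep=cfg.sep)
        digest = hashlib.sha256(Path(cfg.input_path).read_bytes()).hexdigest()
        input_desc = {"events": str(cfg.input_path), "sha256": digest}
    elif cfg.simulate:
        corpus, _truth = generate_practice_panel(list(cfg.simulate))
        input_desc = {"synthetic": [dataclasses.asdict(c) | {"section": c.section.value}
                                    for c in cfg.simulate]}
    else:
        raise ConfigurationError("config must provide an input events file or simulate block")

    sections: dict[str, Any] = {}
    for name in cfg.sections_to_analyze:
        if name not in _SECTION_BY_NAME:
            raise ConfigurationError(f"unknown section {name!r}")
        sub = filter_section(corpus, _SECTION_BY_NAME[name])
        if sub.n_tokens == 0:
            sections[name] = {"error": "no events in section"}
            continue
        sections[name] = _analyse_block(sub, cfg, gof_seed=cfg.seed)

    practices: dict[str, Any] = {}
    if cfg.per_practice:
        target = filter_section(corpus, _SECTION_BY_NAME[cfg.per_practice_section])
        for i, (pid, stratum) in enumerate(sorted(stratify_by_practice(target).items())):
            if stratum.n_tokens == 0:
                continue
            practices[pid] = _analyse_block(stratum, cfg, gof_seed=cfg.seed + i + 1)

    provenance = {
        "input": input_desc,
        "config": {
            "sections_to_analyze": list(cfg.sections_to_analyze),
            "fit": {
                "xmin_strategy": cfg.xmin_strategy,
                "min_tail": cfg.min_tail,
                "beta_max": cfg.beta_max,
                "n_boot": cfg.n_boot,
                "seed": cfg.seed,
            },
            "partition": {"epsilon": cfg.epsilon},
            "per_practice": cfg.per_practice,
        },
        "seed": cfg.seed,
        "version": __version__,
    }
    report = AnalysisReport(sections=sections, practices=practices, provenance=provenance)
    if cfg.output_dir:
        _write_artifacts(report, corpus, cfg)
    return report


def _write_artifacts(report: AnalysisReport, corpus: EncounterCorpus, cfg: AnalysisConfig) -> None:
    import pandas as pd

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json() + "\n", encoding="utf-8")

    table = build_frequency_table(corpus)
    freq = table.counts.rename("count").rename_axis("code").reset_index()
    freq.insert(0, "rank", np.arange(1, len(freq) + 1))
    freq.to_csv(out / "freq_table.tsv", sep="\t", index=False)

    rows = []
    for name, block in report.sections.items():
        for x, p in block.get("pareto", []):
            rows.append((name, int(x), p))
    pd.DataFrame(rows, columns=["section", "x", "tail_prob"]).to_csv(
        out / "pareto_points.tsv", sep="\t", index=False
    )

    rows = []
    for name, block in report.sections.items():
        for w, prof in (block.get("depth_profile") or {}).items():
            for d, pct in prof["percent_at_depth"].items():
                rows.append((name, w, d, pct))
    pd.DataFrame(rows, columns=["section", "weighting", "depth", "percent"]).to_csv(
        out / "depth_profile.tsv", sep="\t", index=False
    )

    if cfg.plots:
        plot_dir = out / "plots"
        plot_dir.mkdir(exist_ok=True)
        for name, block in report.sections.items():
            if "pareto" in block:
                _plot_block(block, name, plot_dir / f"{name}_pareto.png")
        for pid, block in report.practices.items():
            _plot_block(block, pid, plot_dir / f"practice_{pid}_pareto.png")
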