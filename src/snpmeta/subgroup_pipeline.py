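"""End-to-end orchestration: subgroups, HWE filtering, the full analysis
grid, and report files.

The analysis grid crosses five nested/overlapping population subsets
(integrated, Caucasian, Asian, East Asian, China) with two HWE filters
(All studies vs In-HWE, i.e. dropping studies where either arm deviates
from Hardy-Weinberg at the configured alpha) and three genetic models
(allele, dominant, recessive).  Dominant/recessive cells use only
genotype-resolution studies; the allele model uses every study.
Publication-bias tests and leave-one-out sensitivity run per genetic
model on the integrated, unfiltered set.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .bias_sensitivity import (
    BiasTestResult,
    InsufficientStudiesError,
    SensitivityResult,
    begg_test,
    egger_test,
    funnel_data,
    leave_one_out,
)
from .genetic_models import MODELS, build_contrast, continuity_correct, effect_for_study
from .hwe import DEFAULT_ALPHA, DEFAULT_ITERATIONS, flag_hwe, test_corpus
from .meta_engine import MetaResult, UndefinedPoolError, format_p, meta_analyze
from .study_corpus import CorpusError, StudyCorpus

SUBSET_LABELS = ("integrated", "Caucasian", "Asian", "EastAsian", "China")
EAST_ASIAN_COUNTRIES = {"China", "Korea", "Japan"}
FILTERS = ("All", "InHWE")


@dataclass(frozen=True)
class SubsetSpec:
    label: str
    filter: str  # "All" | "InHWE"
    study_ids: tuple[str, ...]


@dataclass
class AnalysisConfig:
    hwe_alpha: float = DEFAULT_ALPHA
    hwe_iterations: int = DEFAULT_ITERATIONS
    seed: int = 0


def _members(corpus: StudyCorpus, label: str) -> list[str]:
    if label == "integrated":
        return [s.study_id for s in corpus]
    if label == "Caucasian":
        return [s.study_id for s in corpus if s.ethnicity == "Caucasian"]
    if label == "Asian":
        return [s.study_id for s in corpus if s.ethnicity == "Asian"]
    if label == "EastAsian":
        return [s.study_id for s in corpus
                if s.ethnicity == "Asian" and s.country in EAST_ASIAN_COUNTRIES]
    if label == "China":
        return [s.study_id for s in corpus if s.country == "China"]
    raise ValueError(f"unknown subset label {label!r}")


def assign_subsets(corpus: StudyCorpus, hwe_flags: dict[str, dict]) -> list[SubsetSpec]:
    """Build the subset x filter membership lists.

    In-HWE variants remove whichever HWE-flagged studies are members of
    that particular subset (per-subset removal).
    """
    flagged = {sid for sid, f in hwe_flags.items() if f["deviates"]}
    specs = []
    for label in SUBSET_LABELS:
        ids = _members(corpus, label)
        specs.append(SubsetSpec(label, "All", tuple(ids)))
        specs.append(SubsetSpec(label, "InHWE",
                                tuple(i for i in ids if i not in flagged)))
    return specs


@dataclass
class AnalysisReport:
    corpus_source: str
    config: AnalysisConfig
    hwe_results: list = field(default_factory=list)
    hwe_flags: dict = field(default_factory=dict)
    subsets: list[SubsetSpec] = field(default_factory=list)
    cells: dict[tuple[str, str, str], MetaResult | None] = field(default_factory=dict)
    bias: dict[str, dict[str, BiasTestResult]] = field(default_factory=dict)
    sensitivity: dict[str, SensitivityResult] = field(default_factory=dict)
    funnels: dict[str, dict] = field(default_factory=dict)


def _eligible_tables(corpus: StudyCorpus, ids, model: str):
    tables = []
    for sid in ids:
        s = corpus[sid]
        if model != "allele" and not s.has_genotypes:
            continue
        tables.append(continuity_correct(build_contrast(s, model)))
    return tables


def run_full_analysis(corpus: StudyCorpus,
                      config: AnalysisConfig | None = None) -> AnalysisReport:
    """HWE testing, the subset x filter x model grid, bias tests and
    leave-one-out sensitivity, deterministically for a fixed seed."""
    if len(corpus) == 0:
        raise CorpusError("empty corpus")
    config = config or AnalysisConfig()
    report = AnalysisReport(corpus_source=corpus.source, config=config)
    report.hwe_results = test_corpus(corpus, alpha=config.hwe_alpha,
                                     iterations=config.hwe_iterations,
                                     seed=config.seed)
    report.hwe_flags = flag_hwe(corpus, alpha=config.hwe_alpha,
                                iterations=config.hwe_iterations,
                                seed=config.seed)
    report.subsets = assign_subsets(corpus, report.hwe_flags)
    for spec in report.subsets:
        for model in MODELS:
            tables = _eligible_tables(corpus, spec.study_ids, model)
            key = (spec.label, spec.filter, model)
            if not tables:
                report.cells[key] = None
                continue
            try:
                report.cells[key] = meta_analyze(tables, subset=spec.label)
            except UndefinedPoolError:
                report.cells[key] = None
    all_ids = [s.study_id for s in corpus]
    for model in MODELS:
        tables = _eligible_tables(corpus, all_ids, model)
        effects = [e for e in (report.cells[("integrated", "All", model)].effects
                               if report.cells[("integrated", "All", model)] else ())]
        report.bias[model] = {}
        try:
            report.bias[model]["egger"] = egger_test(effects)
            report.bias[model]["begg"] = begg_test(effects)
        except (InsufficientStudiesError, ValueError):
            pass
        if effects:
            report.funnels[model] = funnel_data(effects)
        if len(tables) >= 2:
            report.sensitivity[model] = leave_one_out(tables, subset="integrated")
    return report


def _cell_row(label, filt, model, r: MetaResult | None) -> dict:
    if r is None:
        return {"subset": label, "filter": filt, "model": model,
                "status": "not_computable"}
    return {
        "subset": label, "filter": filt, "model": model, "status": "ok",
        "k": r.k, "OR": round(r.pooled_or, 4),
        "ci_low": round(r.ci_low, 4), "ci_high": round(r.ci_high, 4),
        "p_value": format_p(r.p_value),
        "i_squared": f"{r.i_squared:.1f}%", "p_q": f"{r.p_q:.4f}",
        "tau_squared": round(r.tau_squared, 6),
        "effect_model": r.effect_model,
        "association": "significant" if r.significant else "not significant",
    }


def render_reports(report: AnalysisReport, outdir: str | Path) -> dict[str, Path]:
    """Write the results grid, per-study effects, HWE, bias, sensitivity
    and funnel tables plus a JSON bundle and run manifest under outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    rows = [_cell_row(lbl, flt, m, r)
            for (lbl, flt, m), r in report.cells.items()]
    paths["results"] = outdir / "meta_results.tsv"
    pd.DataFrame(rows).to_csv(paths["results"], sep="\t", index=False)

    eff_rows = []
    for (lbl, flt, m), r in report.cells.items():
        if r is None or (lbl, flt) != ("integrated", "All"):
            continue
        for e in r.effects:
            eff_rows.append({"model": m, "study_id": e.study_id,
                             "OR": round(e.or_value, 4),
                             "ci_low": round(e.ci_low, 4),
                             "ci_high": round(e.ci_high, 4),
                             "log_or": round(e.log_or, 6),
                             "se": round(e.se, 6),
                             "p_value": format_p(e.p_value),
                             "corrected": e.corrected})
    paths["effects"] = outdir / "study_effects.tsv"
    pd.DataFrame(eff_rows).to_csv(paths["effects"], sep="\t", index=False)

    hwe_rows = [{"study_id": h.study_id, "arm": h.arm,
                 "chi_sq": round(h.chi_sq, 6),
                 "p_asymptotic": round(h.p_asymptotic, 6),
                 "p_simulated": round(h.p_simulated, 6),
                 "deviates": h.deviates}
                for h in report.hwe_results]
    paths["hwe"] = outdir / "hwe_report.tsv"
    pd.DataFrame(hwe_rows).to_csv(paths["hwe"], sep="\t", index=False)

    bias_rows = []
    for model, tests in report.bias.items():
        for name, b in tests.items():
            bias_rows.append({"model": model, "method": name,
                              "statistic": round(b.statistic, 6),
                              "p_value": round(b.p_value, 4),
                              "k": b.k, "significant": b.significant})
    paths["bias"] = outdir / "bias_tests.tsv"
    pd.DataFrame(bias_rows).to_csv(paths["bias"], sep="\t", index=False)

    sens_rows = []
    for model, sens in report.sensitivity.items():
        for sid, r in sens.refits:
            sens_rows.append({"model": model, "excluded_id": sid,
                              "OR": round(r.pooled_or, 4),
                              "ci_low": round(r.ci_low, 4),
                              "ci_high": round(r.ci_high, 4),
                              "p_value": format_p(r.p_value),
                              "effect_model": r.effect_model})
    paths["sensitivity"] = outdir / "sensitivity.tsv"
    pd.DataFrame(sens_rows).to_csv(paths["sensitivity"], sep="\t", index=False)

    paths["funnel"] = outdir / "funnel_data.json"
    paths["funnel"].write_text(json.dumps(report.funnels, indent=1, sort_keys=True))

    paths["manifest"] = outdir / "run_manifest.json"
    paths["manifest"].write_text(json.dumps({
        "corpus_source": report.corpus_source,
        "seed": report.config.seed,
        "hwe_alpha": report.config.hwe_alpha,
        "hwe_iterations": report.config.hwe_iterations,
        "snpmeta_version": __version__,
        "python": platform.python_version(),
    }, indent=1, sort_keys=True))
    return paths
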