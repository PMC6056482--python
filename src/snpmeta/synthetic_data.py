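"""Synthetic study-corpus generator with known ground truth.

Emulates the structure of a published rs11136000-style study table: k
case-control studies, each with multinomial genotype counts in both arms,
a configurable control minor-allele frequency, a true allele odds ratio
(optionally heterogeneous across studies), Hardy-Weinberg deviation in the
population via an inbreeding coefficient F, a fraction of studies that
report only allele counts, and an optional publication-bias mechanism that
suppresses non-significant studies.

Generative model per study:

- control genotype probabilities with inbreeding F:
  (p² + Fpq, 2pq(1-F), q² + Fpq) for (TT, TC, CC), q = 1 - p;
- case probabilities multiply the control genotype probability by
  ψ^dosage, ψ = exp(study log-OR), then renormalize.  Under HWE this
  multiplicative-dosage model makes the allele-contrast odds ratio exactly
  ψ, so the allele model is the natural ground truth; dominant and
  recessive pooled values on such data are derived quantities.
- study log-ORs are Normal(ln(true_or), τ²) across studies.

A single root seed drives an independent spawned stream per study, so
results do not depend on generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetic_models import effect_for_study
from .study_corpus import GenotypeCounts, StudyCorpus, StudyRecord

#: per-study metadata cycled through simulated corpora so every subgroup
#: (Caucasian / Asian / East Asian / China) is populated.
_FAKE_SITES = [
    ("China", "Asian"), ("USA", "Caucasian"), ("China", "Asian"),
    ("Germany", "Caucasian"), ("Korea", "Asian"), ("France", "Caucasian"),
    ("China", "Asian"), ("Japan", "Asian"), ("UK", "Caucasian"),
    ("India", "Asian"), ("Italy", "Caucasian"), ("Brazil", "Mixed"),
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic study collection.

    Defaults mimic the data regime of the published rs11136000 corpus: a
    common minor allele (MAF 0.3-0.5), k = 50 studies, roughly one third
    reporting allele counts only, a protective true allele OR, and no HWE
    deviation or publication bias unless requested.
    """

    k: int = 50
    true_or: float = 0.85
    tau_squared: float = 0.0
    maf_range: tuple[float, float] = (0.3, 0.5)
    n_case_range: tuple[int, int] = (800, 1200)
    n_control_range: tuple[int, int] = (800, 1200)
    inbreeding_f: float = 0.0
    allele_only_fraction: float = 0.34
    bias_suppression: float = 0.0
    bias_p_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range bounds must lie in (0, 1)")
        if self.tau_squared < 0:
            raise ValueError("tau_squared must be >= 0")
        if not 0.0 <= self.allele_only_fraction <= 1.0:
            raise ValueError("allele_only_fraction must be in [0, 1]")
        if not 0.0 <= self.inbreeding_f < 1.0:
            raise ValueError("inbreeding_f must be in [0, 1)")


def _genotype_probs(p: float, f: float) -> np.ndarray:
    """(TT, TC, CC) probabilities with inbreeding coefficient f."""
    q = 1.0 - p
    probs = np.array([p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q])
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError(f"degenerate genotype probabilities for p={p}, f={f}")
    return probs / probs.sum()


def simulate_study(cfg: SimulationConfig, study_true_logor: float,
                   rng: np.random.Generator, study_id: str = "sim",
                   country: str = "China", ethnicity: str = "Asian",
                   allele_only: bool = False,
                   n_cases: int | None = None,
                   n_controls: int | None = None) -> StudyRecord:
    """Draw one study's genotype counts under the generative model."""
    p = rng.uniform(*cfg.maf_range)
    ctrl_probs = _genotype_probs(p, cfg.inbreeding_f)
    psi = np.exp(study_true_logor)
    case_probs = ctrl_probs * np.array([psi**2, psi, 1.0])
    case_probs /= case_probs.sum()
    if n_cases is None:
        n_cases = int(rng.integers(cfg.n_case_range[0], cfg.n_case_range[1] + 1))
    if n_controls is None:
        n_controls = int(rng.integers(cfg.n_control_range[0],
                                      cfg.n_control_range[1] + 1))
    case_counts = rng.multinomial(n_cases, case_probs)
    ctrl_counts = rng.multinomial(n_controls, ctrl_probs)

    def _arm(counts) -> GenotypeCounts:
        g = GenotypeCounts(n_TT=int(counts[0]), n_TC=int(counts[1]),
                           n_CC=int(counts[2]))
        if allele_only:
            n_t, n_c = g.allele_counts()
            return GenotypeCounts(n_T=n_t, n_C=n_c)
        return g

    return StudyRecord(
        study_id=study_id, first_author="Sim", year=2020, country=country,
        ethnicity=ethnicity,
        resolution="allele_only" if allele_only else "genotype",
        cases=_arm(case_counts), controls=_arm(ctrl_counts),
        platform="synthetic",
    )


def simulate_from_metadata(metadata, cfg: SimulationConfig) -> tuple[StudyCorpus, dict]:
    """Simulate genotype counts onto a real study-metadata table.

    ``metadata`` is a DataFrame with columns study_id, country, ethnicity,
    resolution, n_cases, n_controls (e.g. the packaged 50-study table):
    identifiers, subgroup structure, per-arm sample sizes and genotype
    resolution are taken from the published design, while the genotype
    counts themselves are drawn from the generative model.  This yields a
    synthetic corpus with exactly the published corpus shape.
    """
    root = np.random.SeedSequence(cfg.seed)
    seeds = root.spawn(len(metadata))
    studies, truth_logors = [], []
    for (_, row), ss in zip(metadata.iterrows(), seeds):
        rng = np.random.default_rng(ss)
        true_logor = float(rng.normal(np.log(cfg.true_or),
                                      np.sqrt(cfg.tau_squared)))
        studies.append(simulate_study(
            cfg, true_logor, rng, study_id=row["study_id"],
            country=row["country"], ethnicity=row["ethnicity"],
            allele_only=row["resolution"] == "allele_only",
            n_cases=int(row["n_cases"]), n_controls=int(row["n_controls"])))
        truth_logors.append(true_logor)
    truth = {"true_or": cfg.true_or, "tau_squared": cfg.tau_squared,
             "study_log_or": truth_logors, "seed": cfg.seed}
    return StudyCorpus(studies, source=f"<simulated-from-metadata seed={cfg.seed}>"), truth


def simulate_corpus(cfg: SimulationConfig) -> tuple[StudyCorpus, dict]:
    """Generate a corpus of k studies plus the generating truth record.

    When ``bias_suppression`` > 0, each generated study whose allele-model
    P exceeds ``bias_p_threshold`` is discarded with that probability and
    redrawn (capped), emulating selective publication of significant
    results.
    """
    root = np.random.SeedSequence(cfg.seed)
    study_seeds = root.spawn(cfg.k)
    truth_logors = []
    studies = []
    for i, ss in enumerate(study_seeds):
        rng = np.random.default_rng(ss)
        true_logor = float(rng.normal(np.log(cfg.true_or),
                                      np.sqrt(cfg.tau_squared)))
        country, ethnicity = _FAKE_SITES[i % len(_FAKE_SITES)]
        allele_only = bool(rng.random() < cfg.allele_only_fraction)
        for _attempt in range(100):
            s = simulate_study(cfg, true_logor, rng,
                               study_id=f"sim{i:03d}_{country}",
                               country=country, ethnicity=ethnicity,
                               allele_only=allele_only)
            if cfg.bias_suppression <= 0.0:
                break
            p = effect_for_study(s, "allele").p_value
            if p <= cfg.bias_p_threshold or rng.random() >= cfg.bias_suppression:
                break
        truth_logors.append(true_logor)
        studies.append(s)
    truth = {
        "true_or": cfg.true_or,
        "tau_squared": cfg.tau_squared,
        "study_log_or": truth_logors,
        "seed": cfg.seed,
    }
    return StudyCorpus(studies, source=f"<simulated seed={cfg.seed}>"), truth
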