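"""Genetic-model 2x2 contrasts and per-study odds-ratio effects.

Three standard contrasts are formed from a study's genotype counts, always
orienting the minor allele T as the "exposed" side (so an odds ratio below 1
means the minor allele is protective):

- allele:    T vs C alleles (2N allele observations per arm)
- dominant:  TT + TC carriers vs CC
- recessive: TT vs TC + CC

Per-study effects are Woolf log odds ratios with the usual variance
1/a + 1/b + 1/c + 1/d, Wald confidence intervals and two-sided P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy import stats

from .study_corpus import StudyRecord, ResolutionError

MODELS = ("allele", "dominant", "recessive")

#: 97.5% standard-normal quantile used for all 95% Wald intervals.
Z975 = 1.959964


class EligibilityError(ValueError):
    """Genotype-level contrast requested on an allele-only study."""


class UndefinedEffectError(ValueError):
    """A 2x2 cell is zero; apply the continuity correction first."""


@dataclass(frozen=True)
class FourfoldTable:
    """One study's 2x2 table under one genetic model.

    a = exposed cases, b = unexposed cases, c = exposed controls,
    d = unexposed controls.  Cells may be half-integers after the
    continuity correction.
    """

    a: float
    b: float
    c: float
    d: float
    model: str
    study_id: str = ""
    corrected: bool = False

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class StudyEffect:
    """Per-study log odds ratio with Woolf standard error and Wald CI/P."""

    study_id: str
    model: str
    log_or: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool = False


def build_contrast(s: StudyRecord, model: str) -> FourfoldTable:
    """Form the 2x2 contrast for one study under one genetic model.

    The allele model is available for every study (allele-only studies use
    their published allele counts); dominant and recessive require genotype
    resolution.
    """
    if model not in MODELS:
        raise ValueError(f"unknown genetic model {model!r}")
    if model == "allele":
        a, b = s.cases.allele_counts()
        c, d = s.controls.allele_counts()
    else:
        if not s.has_genotypes:
            raise EligibilityError(
                f"{s.study_id}: {model} model requires genotype resolution"
            )
        if model == "dominant":
            a, b = s.cases.n_TT + s.cases.n_TC, s.cases.n_CC
            c, d = s.controls.n_TT + s.controls.n_TC, s.controls.n_CC
        else:  # recessive
            a, b = s.cases.n_TT, s.cases.n_TC + s.cases.n_CC
            c, d = s.controls.n_TT, s.controls.n_TC + s.controls.n_CC
    return FourfoldTable(a=float(a), b=float(b), c=float(c), d=float(d),
                         model=model, study_id=s.study_id)


def continuity_correct(t: FourfoldTable) -> FourfoldTable:
    """Add 0.5 to all four cells when any cell is zero (Gart correction)."""
    if min(t.a, t.b, t.c, t.d) > 0:
        return t
    return replace(t, a=t.a + 0.5, b=t.b + 0.5, c=t.c + 0.5, d=t.d + 0.5,
                   corrected=True)


def study_effect(t: FourfoldTable) -> StudyEffect:
    """Woolf log-OR, SE, 95% CI and two-sided Wald P for one 2x2 table."""
    if min(t.a, t.b, t.c, t.d) <= 0:
        raise UndefinedEffectError(
            f"{t.study_id}: zero cell in 2x2 table; apply continuity_correct"
        )
    log_or = math.log(t.a * t.d / (t.b * t.c))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    z = log_or / se
    p = 2.0 * stats.norm.sf(abs(z))
    return StudyEffect(
        study_id=t.study_id, model=t.model, log_or=log_or, se=se,
        or_value=math.exp(log_or),
        ci_low=math.exp(log_or - Z975 * se),
        ci_high=math.exp(log_or + Z975 * se),
        p_value=p, corrected=t.corrected,
    )


def effect_for_study(s: StudyRecord, model: str) -> StudyEffect:
    """Convenience: contrast, correct if needed, and estimate in one call."""
    return study_effect(continuity_correct(build_contrast(s, model)))
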