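"""Heterogeneity statistics and pooled-effect estimation.

Heterogeneity is quantified on the Woolf log odds ratios with
inverse-variance weights: Cochran's Q (chi-squared, k-1 df) and
I² = max(0, (Q - (k-1)) / Q) x 100%.

Pooling follows the conventional two-track rule used in genetic
epidemiology meta-analyses: a fixed-effect Mantel-Haenszel pooled odds
ratio (CI from the Robins-Breslow-Greenland variance of its log) unless
heterogeneity is significant — here I² > 50% AND P(Q) < 0.01 — in which
case a DerSimonian-Laird random-effects model is used.  Note that Q, I²
and P(Q) are always computed from the inverse-variance weights even when
the pooled estimate is Mantel-Haenszel, matching the behaviour of the
standard meta-analysis software stack this mirrors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genetic_models import (
    Z975,
    FourfoldTable,
    StudyEffect,
    continuity_correct,
    study_effect,
)

#: model-choice thresholds: random effects iff both are crossed
I2_THRESHOLD = 50.0
PQ_THRESHOLD = 0.01


class UndefinedPoolError(ValueError):
    pass


@dataclass(frozen=True)
class MetaResult:
    """Pooled result for one (subset, filter, genetic model) analysis cell."""

    model: str
    subset: str
    k: int
    pooled_or: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float
    Q: float
    df: int
    p_q: float
    i_squared: float
    tau_squared: float
    effect_model: str  # "fixed_MH" | "random_DL"
    effects: tuple[StudyEffect, ...] = field(default=())

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def cochran_q(effects: list[StudyEffect]) -> tuple[float, int, float]:
    """Cochran's Q, its degrees of freedom, and the chi-squared tail P.

    With fewer than two studies Q is undefined; (0, 0, 1) is returned.
    """
    k = len(effects)
    if k < 2:
        return 0.0, 0, 1.0
    theta = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    theta_hat = float((w * theta).sum() / w.sum())
    q = float((w * (theta - theta_hat) ** 2).sum())
    return q, k - 1, float(stats.chi2.sf(q, df=k - 1))


def i_squared(Q: float, k: int) -> float:
    """I² heterogeneity percentage, (Q - (k-1))/Q x 100, floored at 0."""
    if Q <= 0.0:
        return 0.0
    return max(0.0, (Q - (k - 1)) / Q * 100.0)


def choose_model(Q: float, k: int, p_q: float) -> str:
    """Random effects iff I² > 50% AND P(Q) < 0.01; fixed otherwise."""
    if i_squared(Q, k) > I2_THRESHOLD and p_q < PQ_THRESHOLD:
        return "random_DL"
    return "fixed_MH"


def _wald(log_or: float, se: float) -> tuple[float, float, float, float, float]:
    z = log_or / se
    p = 2.0 * stats.norm.sf(abs(z))
    return (math.exp(log_or), math.exp(log_or - Z975 * se),
            math.exp(log_or + Z975 * se), z, p)


def pool_fixed_mh(tables: list[FourfoldTable], subset: str = "",
                  het: tuple[float, int, float] | None = None,
                  effects: list[StudyEffect] | None = None) -> MetaResult:
    """Mantel-Haenszel fixed-effect pooled OR with RBG confidence interval.

    OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i); the variance of its
    log uses the Robins-Breslow-Greenland estimator, which reduces to the
    Woolf variance for a single table.
    """
    if not tables:
        raise UndefinedPoolError("no tables to pool")
    a = np.array([t.a for t in tables])
    b = np.array([t.b for t in tables])
    c = np.array([t.c for t in tables])
    d = np.array([t.d for t in tables])
    n = a + b + c + d
    R_i, S_i = a * d / n, b * c / n
    R, S = float(R_i.sum()), float(S_i.sum())
    if R <= 0.0 or S <= 0.0:
        raise UndefinedPoolError("empty exposure margins; cannot pool")
    log_or = math.log(R / S)
    P_i, Q_i = (a + d) / n, (b + c) / n
    var = (float((P_i * R_i).sum()) / (2 * R**2)
           + float((P_i * S_i + Q_i * R_i).sum()) / (2 * R * S)
           + float((Q_i * S_i).sum()) / (2 * S**2))
    se = math.sqrt(var)
    or_v, lo, hi, z, p = _wald(log_or, se)
    if effects is None:
        effects = [study_effect(t) for t in tables]
    q, df, p_q = het if het is not None else cochran_q(effects)
    return MetaResult(
        model=tables[0].model, subset=subset, k=len(tables),
        pooled_or=or_v, ci_low=lo, ci_high=hi, z=z, p_value=p,
        Q=q, df=df, p_q=p_q, i_squared=i_squared(q, len(tables)),
        tau_squared=dl_tau_squared(effects) if len(effects) >= 2 else 0.0,
        effect_model="fixed_MH", effects=tuple(effects),
    )


def dl_tau_squared(effects: list[StudyEffect]) -> float:
    """DerSimonian-Laird moment estimate of the between-study variance."""
    k = len(effects)
    if k < 2:
        return 0.0
    q, df, _ = cochran_q(effects)
    w = np.array([1.0 / e.se**2 for e in effects])
    denom = float(w.sum() - (w**2).sum() / w.sum())
    if denom <= 0.0:
        return 0.0
    return max(0.0, (q - df) / denom)


def pool_random_dl(effects: list[StudyEffect], subset: str = "",
                   model: str | None = None) -> MetaResult:
    """DerSimonian-Laird random-effects pooled OR (inverse-variance weights
    1/(SE_i² + τ²))."""
    k = len(effects)
    if k < 2:
        raise UndefinedPoolError("random-effects pooling needs k >= 2")
    q, df, p_q = cochran_q(effects)
    tau2 = dl_tau_squared(effects)
    theta = np.array([e.log_or for e in effects])
    w_star = 1.0 / (np.array([e.se for e in effects]) ** 2 + tau2)
    log_or = float((w_star * theta).sum() / w_star.sum())
    se = math.sqrt(1.0 / float(w_star.sum()))
    or_v, lo, hi, z, p = _wald(log_or, se)
    return MetaResult(
        model=model or effects[0].model, subset=subset, k=k,
        pooled_or=or_v, ci_low=lo, ci_high=hi, z=z, p_value=p,
        Q=q, df=df, p_q=p_q, i_squared=i_squared(q, k), tau_squared=tau2,
        effect_model="random_DL", effects=tuple(effects),
    )


def meta_analyze(tables: list[FourfoldTable], subset: str = "") -> MetaResult:
    """Full analysis of one cell: effects, heterogeneity, model choice, pool."""
    if not tables:
        raise UndefinedPoolError("no tables to analyze")
    tables = [continuity_correct(t) for t in tables]
    effects = [study_effect(t) for t in tables]
    q, df, p_q = cochran_q(effects)
    if choose_model(q, len(tables), p_q) == "random_DL":
        return pool_random_dl(effects, subset=subset, model=tables[0].model)
    return pool_fixed_mh(tables, subset=subset, het=(q, df, p_q),
                         effects=effects)


def format_p(p: float) -> str:
    """Report-table convention: very small P-values print as '<0.0001'."""
    return "<0.0001" if p < 1e-4 else f"{p:.4f}"
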