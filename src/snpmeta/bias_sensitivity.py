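"""Publication-bias diagnostics and leave-one-out sensitivity analysis.

Small-study (publication) bias is probed two ways:

- Egger regression: OLS of the standardized effect θ_i/SE_i on precision
  1/SE_i; under no bias the intercept is zero, tested with a two-sided t
  on k-2 degrees of freedom.
- Begg-Mazumdar rank correlation: Kendall's score between the
  variance-stabilized deviates of the study effects from the pooled effect
  and the study variances, with the continuity-corrected normal
  approximation.

Sensitivity is the classic leave-one-out scheme: the meta-analysis is
refit k times omitting one study each, re-applying the fixed/random model
choice per refit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genetic_models import Z975, FourfoldTable, StudyEffect
from .meta_engine import MetaResult, meta_analyze

BIAS_ALPHA = 0.05


class InsufficientStudiesError(ValueError):
    pass


@dataclass(frozen=True)
class BiasTestResult:
    method: str  # "begg" | "egger"
    statistic: float  # Kendall z or intercept t
    p_value: float
    k: int
    significant: bool
    intercept: float | None = None
    slope: float | None = None
    kendall_score: int | None = None


@dataclass(frozen=True)
class SensitivityResult:
    """Reference all-study fit plus one refit per excluded study."""

    reference: MetaResult
    refits: tuple[tuple[str, MetaResult], ...]  # (excluded study_id, result)

    def influential(self) -> list[str]:
        """Studies whose omission moves the pooled OR outside the reference
        CI or flips the P < 0.05 verdict."""
        out = []
        for sid, r in self.refits:
            moved = not (self.reference.ci_low <= r.pooled_or
                         <= self.reference.ci_high)
            flipped = r.significant != self.reference.significant
            if moved or flipped:
                out.append(sid)
        return out


def egger_test(effects: list[StudyEffect]) -> BiasTestResult:
    """Egger's regression asymmetry test.

    Regresses θ_i/SE_i on 1/SE_i and t-tests the intercept (k-2 df).
    Requires k >= 3 and at least two distinct SEs.
    """
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError("Egger's test needs k >= 3")
    se = np.array([e.se for e in effects])
    theta = np.array([e.log_or for e in effects])
    x = 1.0 / se
    y = theta / se
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate design: all precisions identical")
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    slope = float(((x - xbar) * (y - ybar)).sum()) / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    s2 = float((resid**2).sum()) / (k - 2)
    se_intercept = math.sqrt(s2 * (1.0 / k + xbar**2 / sxx))
    t = intercept / se_intercept if se_intercept > 0 else 0.0
    p = 2.0 * stats.t.sf(abs(t), df=k - 2)
    return BiasTestResult(method="egger", statistic=t, p_value=p, k=k,
                          significant=p < BIAS_ALPHA,
                          intercept=intercept, slope=slope)


def begg_test(effects: list[StudyEffect]) -> BiasTestResult:
    """Begg-Mazumdar rank-correlation asymmetry test.

    Correlates the variance-stabilized deviates
    u_i = (θ_i - θ̂) / sqrt(SE_i² - 1/Σw) with the variances SE_i² using
    Kendall's score; z uses the continuity-corrected normal approximation
    z = (|S| - 1)/sqrt(k(k-1)(2k+5)/18).
    """
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError("Begg's test needs k >= 3")
    se2 = np.array([e.se**2 for e in effects])
    theta = np.array([e.log_or for e in effects])
    w = 1.0 / se2
    theta_hat = float((w * theta).sum() / w.sum())
    v_star = se2 - 1.0 / float(w.sum())
    if np.any(v_star <= 0):
        warnings.warn("non-positive stabilized variance; ranking raw deviates")
        u = theta - theta_hat
    else:
        u = (theta - theta_hat) / np.sqrt(v_star)
    s = 0
    for i in range(k):
        for j in range(i + 1, k):
            s += int(np.sign(u[j] - u[i]) * np.sign(se2[j] - se2[i]))
    var = k * (k - 1) * (2 * k + 5) / 18.0
    z = 0.0 if s == 0 else (abs(s) - 1) / math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(z))
    return BiasTestResult(method="begg", statistic=z, p_value=p, k=k,
                          significant=p < BIAS_ALPHA, kendall_score=s)


def funnel_data(effects: list[StudyEffect],
                pooled_log_or: float | None = None,
                n_grid: int = 50) -> dict:
    """Plot-ready funnel data: per-study (log-OR, SE) points, the pooled
    reference line, and pseudo-95% boundaries θ̂ ± 1.959964·SE over an SE
    grid from 0 to the largest observed SE."""
    if not effects:
        raise InsufficientStudiesError("funnel needs at least one study")
    se = np.array([e.se for e in effects])
    theta = np.array([e.log_or for e in effects])
    if pooled_log_or is None:
        w = 1.0 / se**2
        pooled_log_or = float((w * theta).sum() / w.sum())
    se_grid = np.linspace(0.0, float(se.max()), n_grid)
    return {
        "study_id": [e.study_id for e in effects],
        "log_or": theta.tolist(),
        "se": se.tolist(),
        "pooled_log_or": pooled_log_or,
        "boundary_se": se_grid.tolist(),
        "boundary_low": (pooled_log_or - Z975 * se_grid).tolist(),
        "boundary_high": (pooled_log_or + Z975 * se_grid).tolist(),
    }


def leave_one_out(tables: list[FourfoldTable], subset: str = "") -> SensitivityResult:
    """Refit the meta-analysis k times, each omitting one study; the
    fixed/random model choice is re-applied in every refit."""
    if len(tables) < 2:
        raise InsufficientStudiesError("leave-one-out needs k >= 2")
    reference = meta_analyze(tables, subset=subset)
    refits = []
    for i, t in enumerate(tables):
        rest = tables[:i] + tables[i + 1:]
        refits.append((t.study_id, meta_analyze(rest, subset=subset)))
    return SensitivityResult(reference=reference, refits=tuple(refits))
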