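"""Hardy-Weinberg equilibrium testing with Monte-Carlo P-values.

For each study arm (cases, controls) with genotype counts (TT, TC, CC), the
test statistic is the plain Pearson chi-squared of the observed genotype
counts against the HWE expectations n·p̂², 2n·p̂q̂, n·q̂² (allele frequency
p̂ estimated from the sample; no Yates continuity correction).

The reference P-value is Monte-Carlo: conditional on the observed allele
counts, the 2n alleles are randomly re-paired into n genotypes (a uniform
permutation null) and the chi-squared statistic recomputed each iteration.
Because the allele counts are fixed, the statistic depends on the simulated
heterozygote count alone, so iterations vectorise.  An exact conditional
P-value by full enumeration of the heterozygote count (Levene's
distribution) is provided as the small-sample oracle.

A study "deviates" when either arm's simulated P falls below alpha
(default 0.01); HWE-filtered ("In HWE") analyses drop the whole study.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .study_corpus import GenotypeCounts, ResolutionError, StudyCorpus

DEFAULT_ALPHA = 0.01
DEFAULT_ITERATIONS = 10_000
_EPS = 1e-12


@dataclass(frozen=True)
class HweResult:
    study_id: str
    arm: str  # "cases" | "controls"
    chi_sq: float
    p_asymptotic: float
    p_simulated: float
    iterations: int
    seed: int
    deviates: bool


def _chi_components(n_tt: int, n_tc: int, n_cc: int):
    n = n_tt + n_tc + n_cc
    n_t = 2 * n_tt + n_tc
    p_hat = n_t / (2 * n)
    q_hat = 1.0 - p_hat
    expected = np.array([n * p_hat**2, 2 * n * p_hat * q_hat, n * q_hat**2])
    return n, n_t, p_hat, expected


def _chisq_from_het(h, n_t, n_c, expected):
    """Chi-squared as a function of heterozygote count, allele counts fixed."""
    h = np.asarray(h, dtype=float)
    n_tt = (n_t - h) / 2.0
    n_cc = (n_c - h) / 2.0
    obs = np.stack([n_tt, h, n_cc])
    return ((obs - expected[:, None]) ** 2 / expected[:, None]).sum(axis=0)


def hwe_chisq(g: GenotypeCounts) -> tuple[float, float]:
    """Pearson HWE chi-squared (no continuity correction) and 1-df tail P.

    Monomorphic samples (p̂ in {0, 1}) return (0.0, 1.0) by convention: no
    departure from HWE is observable without both alleles present.
    """
    if not g.has_genotypes:
        raise ResolutionError("HWE test requires genotype counts")
    n, n_t, p_hat, expected = _chi_components(g.n_TT, g.n_TC, g.n_CC)
    if n < 1:
        raise ValueError("empty sample")
    if p_hat in (0.0, 1.0):
        return 0.0, 1.0
    obs = np.array([g.n_TT, g.n_TC, g.n_CC], dtype=float)
    chi = float(((obs - expected) ** 2 / expected).sum())
    return chi, float(stats.chi2.sf(chi, df=1))


def hwe_exact_p(g: GenotypeCounts) -> float:
    """Exact conditional HWE P by enumerating the heterozygote count.

    Under random pairing of the 2n observed alleles, the heterozygote count
    h follows Levene's distribution
    P(h) = n! n_T! n_C! 2^h / [(2n)! n_TT! h! n_CC!]; the P-value sums the
    probabilities of all h whose chi-squared meets or exceeds the observed.
    """
    if not g.has_genotypes:
        raise ResolutionError("HWE test requires genotype counts")
    n, n_t, p_hat, expected = _chi_components(g.n_TT, g.n_TC, g.n_CC)
    if p_hat in (0.0, 1.0):
        return 1.0
    n_c = 2 * n - n_t
    chi_obs, _ = hwe_chisq(g)
    hs = np.arange(n_t % 2, min(n_t, n_c) + 1, 2)
    lg = special.gammaln
    log_p = (
        lg(n + 1) + lg(n_t + 1) + lg(n_c + 1) - lg(2 * n + 1)
        + hs * np.log(2.0)
        - lg((n_t - hs) / 2 + 1) - lg(hs + 1) - lg((n_c - hs) / 2 + 1)
    )
    pmf = np.exp(log_p - log_p.max())
    pmf /= pmf.sum()
    chi_all = _chisq_from_het(hs, n_t, n_c, expected)
    return float(pmf[chi_all >= chi_obs - _EPS].sum())


def hwe_simulated_p(
    g: GenotypeCounts,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    study_id: str = "",
    arm: str = "",
    alpha: float = DEFAULT_ALPHA,
) -> HweResult:
    """Monte-Carlo HWE test by random re-pairing of the observed alleles.

    Each iteration shuffles the 2n-allele vector and pairs consecutive
    entries into genotypes; the simulated P is (1 + #{chi_sim >= chi_obs})
    / (1 + iterations), so it is never exactly zero.  Reproducible for a
    fixed seed.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not g.has_genotypes:
        raise ResolutionError("HWE test requires genotype counts")
    n, n_t, p_hat, expected = _chi_components(g.n_TT, g.n_TC, g.n_CC)
    chi_obs, p_asym = hwe_chisq(g)
    if p_hat in (0.0, 1.0):
        return HweResult(study_id, arm, 0.0, 1.0, 1.0, iterations, seed, False)
    n_c = 2 * n - n_t
    rng = np.random.default_rng(seed)
    alleles = np.zeros(2 * n, dtype=np.int8)
    alleles[:n_t] = 1
    exceed = 0
    chunk = max(1, min(iterations, 64_000_000 // (2 * n)))
    done = 0
    while done < iterations:
        b = min(chunk, iterations - done)
        mat = np.tile(alleles, (b, 1))
        mat = rng.permuted(mat, axis=1)
        hets = (mat[:, 0::2] != mat[:, 1::2]).sum(axis=1)
        chi_sim = _chisq_from_het(hets, n_t, n_c, expected)
        exceed += int((chi_sim >= chi_obs - _EPS).sum())
        done += b
    p_sim = (1 + exceed) / (1 + iterations)
    return HweResult(study_id, arm, chi_obs, p_asym, p_sim, iterations, seed,
                     p_sim < alpha)


def _arm_seed(root_seed: int, study_id: str, arm: str) -> int:
    """Stable per-(study, arm) seed so corpus order never changes results."""
    h = zlib.crc32(f"{study_id}/{arm}".encode())
    return int(np.random.SeedSequence([root_seed, h]).generate_state(1)[0] % (2**31))


def test_corpus(
    corpus: StudyCorpus,
    alpha: float = DEFAULT_ALPHA,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
) -> list[HweResult]:
    """Run the Monte-Carlo HWE test on both arms of every genotype study."""
    results = []
    for s in corpus:
        if not s.has_genotypes:
            continue
        for arm_name, arm in (("cases", s.cases), ("controls", s.controls)):
            results.append(
                hwe_simulated_p(arm, iterations=iterations,
                                seed=_arm_seed(seed, s.study_id, arm_name),
                                study_id=s.study_id, arm=arm_name, alpha=alpha)
            )
    return results


def flag_hwe(
    corpus: StudyCorpus,
    alpha: float = DEFAULT_ALPHA,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
) -> dict[str, dict]:
    """Per-study HWE deviation flags.

    Returns ``{study_id: {"case_deviates", "control_deviates", "deviates",
    "testable"}}``; allele-only studies are marked untestable and never
    flagged.  A study deviates when either arm does.
    """
    flags: dict[str, dict] = {
        s.study_id: {"testable": s.has_genotypes, "case_deviates": False,
                     "control_deviates": False, "deviates": False}
        for s in corpus
    }
    for r in test_corpus(corpus, alpha=alpha, iterations=iterations, seed=seed):
        key = "case_deviates" if r.arm == "cases" else "control_deviates"
        flags[r.study_id][key] = r.deviates
        flags[r.study_id]["deviates"] |= r.deviates
    return flags
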