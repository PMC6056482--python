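# Methods

## Data model

One row per GWAS case-control study of a biallelic SNP (minor allele T,
major allele C). Studies carry either genotype counts (TT, TC, CC) per arm
or allele counts (T, C) only, recorded by a resolution flag; counts are
exact integers throughout, and allele counts derived from genotypes obey
n_T = 2·TT + TC. The packaged `table1_studies.tsv` holds the real
50-study rs11136000 metadata (identifiers, country, ethnicity, per-arm
sample sizes, platform, resolution). Per-study genotype counts appeared
only in a non-redistributable journal supplement, so analyses that need
counts run on synthetic corpora; `simulate_from_metadata` grafts simulated
counts onto the real design so subgroup structure, sample sizes and the
33/17 genotype/allele-only split are exactly the published ones.

## Per-study effects

The three genetic-model contrasts (allele T vs C; dominant TT+TC vs CC;
recessive TT vs TC+CC) are 2×2 tables with the minor-allele side as
"exposed", so OR < 1 is protective. The allele table formed from genotype
counts treats the 2N alleles as independent observations — the standard
simplification for allele-contrast meta-analysis, and the only reading
under which allele-only studies are poolable with genotype studies.
Per-study effects are Woolf: ln OR = ln(ad/bc), SE = √(Σ 1/cell), 95% CI
with the z multiplier 1.959964 (not 1.96, to match reference
implementations at printed precision), two-sided Wald P. Zero cells get
the Gart correction (0.5 added to all four cells of the affected table
only); the source analyses are silent on zero-cell handling, and this is
the mainstream default.

## Hardy–Weinberg testing

Per arm, Pearson χ² with 1 df against expected counts n p̂², 2n p̂q̂,
n q̂² (p̂ from the sample; no Yates correction). Monomorphic arms return
χ² = 0, P = 1 by convention. The reference P-value is Monte-Carlo: holding
the observed allele counts fixed, the 2n alleles are uniformly re-paired
into n genotypes and χ² recomputed per iteration (default 10,000). Because
allele counts are fixed, χ² is a function of the heterozygote count alone,
which lets iterations run vectorised. The estimator is (1 + #{χ²_sim ≥
χ²_obs})/(1 + B), never exactly zero. An exact conditional P by full
enumeration of the heterozygote count (Levene's distribution, computed in
log space) serves as the small-sample oracle; tests require Monte-Carlo
and enumeration to agree within three Monte-Carlo standard errors. A
study "deviates" at α = 0.01 when either arm does; "In HWE" analyses drop
the whole study, removed per subset from whichever subsets it belongs to.
Per-(study, arm) seeds are derived from the root seed and the study id, so
results are independent of corpus order.

## Heterogeneity, pooling and model choice

Q is computed from inverse-variance weights on the Woolf log-ORs,
P(Q) from χ²(k−1), and I² = max(0, (Q−(k−1))/Q)·100. Q, I² and P(Q) are
always the inverse-variance versions even when the pooled estimate is
Mantel–Haenszel, matching the behaviour of the standard meta-analysis
software stack (verified against R metafor to ~1e-9 on frozen toy values).
The pooled estimate is fixed-effect Mantel–Haenszel (CI from the
Robins–Breslow–Greenland variance, which reduces to Woolf at k = 1) unless
I² > 50% **and** P(Q) < 0.01 — the conjunction is deliberate — in which
case DerSimonian–Laird random effects is used: τ² = max(0,
(Q−(k−1))/(Σw − Σw²/Σw)), weights 1/(SE² + τ²). With k = 1 the MH pool is
the study's crude OR; Q is reported as 0 with df 0 and P 1. Report tables
print P < 1e-4 as "<0.0001" while retaining full precision internally.

## Subgroups

Five subsets: integrated (all studies, including the African, American and
mixed-population studies that never get their own subset), Caucasian and
Asian by ethnicity label, East Asian = Asian studies from China, Korea or
Japan, China by country. Dominant/recessive cells use genotype-resolution
members only. The full grid is 5 subsets × 2 HWE filters × 3 models = 30
cells; empty cells are marked not-computable and the run continues.

## Publication bias and sensitivity

Egger: OLS of θᵢ/SEᵢ on 1/SEᵢ, two-sided t on the intercept with k−2 df
(closed-form normal equations; cross-checked against statsmodels OLS and
R metafor's classic-form regtest). Begg–Mazumdar: Kendall score between
the variance-stabilised deviates uᵢ = (θᵢ−θ̂)/√(SEᵢ²−1/Σw) and the
variances SEᵢ², z = (|S|−1)/√(k(k−1)(2k+5)/18) with continuity
correction; if some stabilised variance is non-positive the raw deviates
are ranked with a warning. Both require k ≥ 3 and use α = 0.05. Funnel
export gives per-study (ln OR, SE), the pooled reference and pseudo-95%
boundaries over an SE grid. Leave-one-out refits the full analysis k
times (model choice re-applied per refit); a study is "influential" when
its omission moves the pooled OR outside the all-study CI or flips the
P < 0.05 verdict — the source analyses report the conclusion but not
their criterion, so this operationalisation is the package's own.
Bias tests run on the same eligible study sets used for pooling (all
studies for allele; genotype-resolution for dominant/recessive).

## Synthetic-data generator

Per study: control MAF p ~ U(0.3, 0.5) (the common-minor-allele regime of
the real corpus); control genotype probabilities (p²+Fpq, 2pq(1−F),
q²+Fpq) with inbreeding coefficient F (default 0 = HWE); case
probabilities multiply the control probabilities by ψ^dosage,
ψ = exp(study log-OR), and renormalise — under HWE this makes the allele
OR exactly ψ, so the allele contrast is the single coherent ground truth
and dominant/recessive pooled values are derived quantities. Study
log-ORs are N(ln OR_true, τ²); counts are multinomial draws. Defaults:
k = 50 studies, true OR 0.85 (protective, matching the magnitude of the
real corpus), τ² = 0, 800–1200 individuals per arm, 34% allele-only
(17/50 as published), no bias suppression. Optional publication bias
discards a study with P > 0.05 with the configured probability and
redraws. A root SeedSequence spawns one stream per study, so generation
is order-independent and fully reproducible.

What the generator does not emulate: linkage disequilibrium, covariates,
population stratification within a study, genotyping error structure, or
correlated case/control arms. Passing calibration on this generator shows
the estimators are correct and well-calibrated under clean multinomial
sampling; it does not certify behaviour under real-data artefacts such as
differential genotyping error.

## Numerical choices and problem sizes

Counts are exact integers until effect estimation; all distribution tails
come from scipy (norm, chi2, t). Q-test and Egger calibration use 500 and
1,000 replicates at k = 50; HWE calibration uses 10,000 Monte-Carlo
iterations in the analysis drivers and acceptance script, 2,000–4,000 in
unit tests, sizes chosen to keep Monte-Carlo error well inside the
asserted tolerances. Measured operating characteristics (seed 20180723):
Q type-I error 0.0100 at nominal 0.01, Egger 0.0510 at nominal 0.05, HWE
arm flag rate 0.010 at α = 0.01 under equilibrium, HWE power 0.980 at
F = 0.2 with 500–800 per arm.

## Known limitations

- The allele model's independent-alleles assumption slightly understates
  per-study variance when genotypes deviate from HWE.
- The Begg normal approximation is used at all k; no exact permutation
  P for very small k.
- No Peto pooling, Hartung–Knapp adjustment, trim-and-fill or
  meta-regression; the pipeline covers exactly the published analysis
  chain.
- Published pooled values can only be checked once the supplementary
  per-study counts are obtained and transcribed into the corpus TSV
  format; the pipeline accepts such a file unchanged via
  `read_corpus` / `snpmeta run`.
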