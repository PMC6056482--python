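# snpmeta

Case-control SNP meta-analysis from study-level genotype counts, built
around the CLU rs11136000 / Alzheimer's disease corpus: 50 published GWAS
case-control studies totalling 28,464 AD cases and 45,784 controls across
Caucasian, Asian, African, American and mixed populations.

For a biallelic SNP with minor allele T and major allele C, each study
contributes genotype counts (TT, TC, CC) — or, for 17 of the 50 studies,
allele counts only — in cases and controls. The package implements the
complete analysis chain a genetic-epidemiology meta-analysis runs over such
a table:

- **Genetic-model contrasts**: allele (T vs C), dominant (TT+TC vs CC) and
  recessive (TT vs TC+CC) 2×2 tables, oriented so OR < 1 means the minor
  allele is protective; Woolf per-study estimates
  ln OR = ln(ad/bc), SE = √(1/a + 1/b + 1/c + 1/d), with a 0.5
  continuity correction on zero cells.
- **Hardy–Weinberg testing**: Pearson χ² (no continuity correction) per
  study arm against n p̂², 2n p̂q̂, n q̂², with Monte-Carlo P-values from
  random re-pairing of the observed alleles (10,000 iterations, α = 0.01)
  and an exact Levene-enumeration oracle; studies deviating in either arm
  are dropped from the "In HWE" reruns.
- **Heterogeneity**: Cochran's Q on inverse-variance weights and
  I² = max(0, (Q − (k−1))/Q) × 100%.
- **Pooling**: Mantel–Haenszel fixed-effect OR with the
  Robins–Breslow–Greenland variance, switching to DerSimonian–Laird random
  effects exactly when I² > 50% **and** P(Q) < 0.01.
- **Subgroups**: the full grid of {integrated, Caucasian, Asian, East
  Asian, China} × {All, In HWE} × {allele, dominant, recessive}.
- **Publication bias and sensitivity**: Egger regression (intercept t-test,
  k−2 df), Begg–Mazumdar rank correlation (continuity-corrected normal
  approximation), funnel-plot data export, and leave-one-out refits.
- **Synthetic data**: a ground-truth generator (multiplicative allele-dosage
  risk, configurable MAF, between-study τ², inbreeding F for HWE deviation,
  allele-only studies, publication-bias suppression) so every stage is
  testable without restricted data.

The packaged `table1_studies.tsv` carries the real 50-study metadata
(sample sizes, ethnicity, country, platform, genotype resolution). The
per-study genotype counts were published only as a journal supplement and
are not redistributed; corpora with counts are simulated onto the real
design (`simulate_from_metadata`), so all pooled ORs printed below are from
synthetic, labelled data with known truth.

## Worked example

```
python analysis/01_summarize_studies.py   # published corpus composition
python analysis/02_simulate_corpus.py     # synthetic counts on the real design
python analysis/03_run_pipeline.py        # HWE + full grid + bias + sensitivity
python analysis/04_calibration.py         # type-I error / recovery / power
```

`03_run_pipeline.py` prints, for a corpus simulated with true allele
OR = 0.85 on the published 50-study design (seed 20180723):

```
HWE-flagged studies (0): none

integrated population, all studies:
    model  k     OR  ci_low  ci_high p_value i_squared effect_model association
   allele 50 0.8665  0.8467   0.8867 <0.0001      4.0%     fixed_MH significant
 dominant 33 0.8413  0.8110   0.8727 <0.0001     10.0%     fixed_MH significant
recessive 33 0.8045  0.7627   0.8486 <0.0001      0.0%     fixed_MH significant
bias (allele): Begg P=0.97, Egger P=0.56
leave-one-out (allele): no influential study
```

Reading it: the allele model pools all 50 studies (allele-only studies
join via their published allele counts; dominant/recessive use the 33
genotype-resolution studies), heterogeneity is low (I² ≤ 10%), so the
fixed-effect Mantel–Haenszel OR is reported and recovers the generating
truth 0.85 inside its CI; neither bias test approaches significance on
unbiased synthetic data, and no single study moves the pooled OR outside
the all-study CI. `04_calibration.py` prints the measured operating
characteristics (Q-test type-I error 0.0100 at nominal 0.01 over 500
replicates; Egger 0.0510 at nominal 0.05 over 1,000; HWE arm flag rate
0.010 in equilibrium and power 0.980 at F = 0.2).

A `snpmeta` CLI wraps the same library: `snpmeta simulate`, `snpmeta run`,
`snpmeta hwe`, `snpmeta bias` (see `--help`).

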