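# Methods

## The estimator

`fstscan` estimates per-SNP multi-population F<sub>ST</sub> with a
gamete-level nested ANOVA. Every diploid genotype is viewed as two gametes
carrying a 0/1 indicator for the counted allele, and the indicator variance
is decomposed into three strata: among populations (MSP), among individuals
within populations (MSI), and among gametes within individuals (MSG), with
degrees of freedom n−1, S1−n and S1 (S1 = genotyped individuals at the
locus, n = non-empty populations). Writing s_i, p_i and h_i for the
per-population sample size, counted-allele frequency and observed
heterozygote proportion, the sums of squares collapse to closed forms:

```
SSP = Σ 2 s_i (p_i − p̄)²             p̄ = Σ s_i p_i / S1
SSI = Σ (2 s_i p_i(1−p_i) − s_i h_i/2)
SSG = Σ s_i h_i / 2
```

and with n_c = (S1 − S2/S1)/(n−1), S2 = Σ s_i²,

```
Fst = (MSP − MSI) / (MSP + (n_c − 1) MSI + n_c MSG).
```

The closed forms are verified in the test suite against an independent
brute-force oracle that literally expands every genotype into two gamete
indicators and sums squares over gametes; agreement is required to 1e−12 on
hundreds of random datasets with missing data.

Properties and conventions:

- **Missing data.** s_i, S1, S2, n and n_c are recomputed per locus from
  non-missing calls; populations with no data at a locus are dropped and n
  shrinks. Deleting an individual that is missing at a locus provably does
  not change that locus's estimate (tested).
- **Degeneracy.** A locus is UNDEFINED when fewer than two populations have
  data, when every population is a single individual (S1 = n leaves MSI
  without degrees of freedom), or when the denominator is zero, which
  happens exactly when the locus is monomorphic in the analysed sample.
  UNDEFINED loci are excluded from all distributions and never flagged.
- **Negative estimates are retained.** Truncating at zero would bias the
  empirical distribution from which outlier thresholds are taken.
- **Numerics.** SSI can come out a rounding error below zero in the closed
  form; magnitudes smaller than 1e−12 are clamped to zero. Defined
  estimates never exceed 1 (algebraic consequence of MSI, MSG ≥ 0, n_c ≥ 1);
  equality holds exactly for fixed differences (MSI = MSG = 0).
- **Allele and label invariance.** Swapping which allele is counted, or
  permuting population labels, leaves the estimate unchanged (tested to
  1e−12). The reader's lexicographic allele-coding convention therefore
  only affects reporting, never estimates.
- **Summaries.** The per-grouping summary is the arithmetic mean and SD of
  defined per-locus estimates; a ratio-of-sums multilocus estimate
  (Σ numerators / Σ denominators) is also reported but is never used for
  thresholds.
- **Sex chromosomes** are treated as diploid autosomal throughout; X-linked
  markers simply appear as another chromosome in the scan track.

## Quality control

Three marker filters run sequentially, each counted on the survivors of the
previous step: (1) unmapped markers (chromosome "0"/empty or position 0);
(2) pooled MAF strictly below 0.05; (3) call rate strictly below 0.90.
Boundary values survive (strict `<` on both thresholds — MAF exactly 0.05
and call rate exactly 0.90 are retained). MAF is pooled over all
individuals regardless of breed, the standard chip-QC behaviour.
Individuals are never removed. A marker with zero calls has undefined MAF;
it passes the MAF stage and is removed at the call-rate stage, so removal
attribution stays meaningful. Running QC twice removes nothing the second
time (tested).

## Outlier calling

The threshold at quantile q over N defined values is the 1-based order
statistic of rank ⌈qN⌉ — always an element of the value set, never an
interpolation — and outliers are *strictly* greater. With distinct values
this selects exactly N − ⌈qN⌉ loci (446 of 44,652 at q = 0.99); with ties at
the threshold it can select fewer, never more. Thresholds are computed on
the pooled genome-wide distribution including sex chromosomes. Raising q
can only shrink the outlier set (tested).

The distance diagnostic bins same-chromosome SNP pairs by separation
(default 50 kb bins to 1 Mb), subsamples each bin to a cap (default 10,000
pairs) with a seeded generator, and computes the correlation of the two
members' F<sub>ST</sub> values with pairs entered symmetrically. Bins with
fewer than 10 pairs are reported empty. Full enumeration of all ~10⁹ pairs
is deliberately avoided; the cap plus seeding keeps the diagnostic
deterministic and fast.

## Gene mapping

A SNP belongs to a gene when its position lies within the annotated span
(UTRs + introns + coding) extended by `flank_bp` on each side. The flank is
a required surfaced parameter (default 5,000 bp, recorded in output
headers) because annotation conventions for "upstream/downstream" vary and
no constant deserves to be implicit. Gene sub-regions are not distinguished:
membership in the flanked span is equivalent to the union of sub-region
rules and adds no information to the report. Contiguous-outlier runs count
flagged SNPs at consecutive positions in genome map order (any unflagged
marker, or a flagged marker not assigned to the gene, breaks the run).
Flagged SNPs with no gene go to an intergenic list, so counts conserve.
Interval lookup uses per-chromosome interval trees.

## PCA

Missing calls are imputed to the per-marker mean dosage (contributing
nothing to the centred covariance); columns are centred by 2p̂ and scaled by
√(2p̂(1−p̂)) — the drift-scaled standardization that is standard in
population genetics because it equalises the expected drift variance per
locus. Monomorphic and fully-missing markers are dropped. Components come
from an SVD; variance fractions are eigenvalue shares of the total, and a
deterministic sign convention (loading sums non-negative) makes output
reproducible.

## The synthetic-data generator

The generator emulates a multi-breed SNP-chip study: nine breeds with
sample sizes 35, 22, 23, 25, 24, 40, 18, 26, 22 (235 individuals), uniform
ancestral frequencies on [0.05, 0.95], Balding–Nichols drift per population
(population frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F), so
Var = F·p(1−p)), and Hardy–Weinberg genotypes within populations. Defaults:

- `drift_F = 0.37`, matching the strong inter-breed differentiation typical
  of divergent pig breeds; parameter-recovery tests run at F = 0.2, where
  mean per-locus F<sub>ST</sub> recovers F within 0.02 on 5,000 loci.
- `n_loci = 64,135` with planted defects 8,383 unmapped / 8,391 low-MAF /
  2,709 low-call-rate, leaving exactly 44,652 markers after QC. The input
  total is the package's own choice: the per-step removal counts and the
  44,652-marker analysis set (the number every downstream quantity depends
  on) cannot all be reconciled with a 62,123-marker chip, so the generator
  fixes the removals and the post-QC denominator and lets the input total
  follow.
- 100 planted selected loci, fixed-difference mode (frequency 0.98 in the
  commercial breeds, 0.02 elsewhere); a boosted-drift mode redraws with a
  stronger F instead.
- background missing-call rate 0.002; call-rate defects mask 10.5–25% of
  individuals, safely past the 90% threshold.

Defect classes are mutually exclusive, and every non-defect locus is
guaranteed to survive QC: loci whose realized pooled MAF falls below the
floor are redrawn (ancestral frequency from the central range, then
genotypes). This mirrors chip ascertainment — assayed SNPs are selected to
be polymorphic — and makes the post-QC marker count and QC report exactly
predictable, which the acceptance checks rely on. The conditioning slightly
depletes low-MAF neutral loci relative to the unconditioned drift model;
parameter-recovery tolerances absorb the effect.

Markers are tiled evenly over an approximate pig karyotype (18 autosomes +
X, ~2.5 Gb); an `ld_block_size > 1` makes consecutive loci share one
population-frequency draw (plus N(0, 0.01) jitter), inducing the
F<sub>ST</sub> correlation decay with distance that the diagnostic detects.
Everything flows from a single seeded generator in a fixed draw order, so
identical configs give byte-identical PED/MAP/truth outputs.

**What the simulator does not emulate:** real linkage disequilibrium decay
(blocks are rectangular, not recombination-driven), chip ascertainment bias
beyond the polymorphism guarantee, hierarchical population structure
(breeds drift independently from one ancestral pool, so PCA variance
concentrates less in PC1 than in real breed panels), genotyping error, and
sex-aware X-chromosome dosages. Passing tests therefore demonstrate
correctness of the estimator, filters and thresholds under a clean island
model — not that real chip data meet those assumptions.

## Problem sizes and determinism

Test and acceptance runs use the study-scale panel (235 × ~64k markers,
~seconds per scan thanks to vectorised per-population tallies) and smaller
fixtures where scale adds nothing. The full pipeline (simulate → QC → three
groupings → outliers → gene report → PCA → distance correlation) is
deterministic given config + seed: fixed float formatting, no timestamps in
the manifest, seeded subsampling. Two runs with the same seed produce
byte-identical TSVs (tested at full scale).

## Open design choices made here

- Breed → population groupings support merged pools (pairwise contrasts
  such as Chinese-indigenous vs European-commercial) and breed exclusion
  (contrasts using a subset of breeds); the Yutai developed breed is
  grouped with the Chinese pool in the bundled example contrast.
- MAF is computed before the call-rate filter; the reverse order is not
  distinguishable from published removal counts, and the sequential-as-
  printed order is the only self-consistent reading.
- PED alleles are coded deterministically (count the lexicographically
  larger observed allele). Markers monomorphic in the sample cannot carry
  their unobserved second allele through a PED round trip; they are read
  back with allele_a1 = "0".
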