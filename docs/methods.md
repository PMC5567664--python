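# Methods

This note records the models behind `tetraqtl`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the numerical choices a maintainer would want to know.

## The pooled case-control design

For each trait (TSC, TY, TSY) two genotype groups are assembled from
adjusted entry means: the `n_case` highest (HIGH, cases) and, from the
remaining genotypes, the `n_control` lowest (LOW, controls). Ties at a
cutoff break by ascending genotype identifier, which makes selection
deterministic and invariant to the row order of the phenotype table;
drawing controls from the remainder guarantees disjoint groups even when a
tie block spans both cutoffs. Group contrasts are verified with Welch
two-sample t-tests for all three traits; the cross-trait contrasts are
reported but never gate the analysis (pools selected for starch content
legitimately may or may not differ for yield).

## Differential allele-frequency tests

**Pooled-reads arm.** Reads from the members of a pool are summed per SNP;
the 2×2 table (alt/ref × case/control) is tested with a two-sided Fisher
exact test. Two-sidedness follows the minimum-likelihood rule: the p-value
is the sum of hypergeometric probabilities, at fixed margins, of every
table no more probable than the observed one. The implementation works on
integer weights `C(n1, x)·C(n2, K−x)` (Python arbitrary-precision
integers), so tie comparisons are exact and the result agrees with
exhaustive enumeration to the last floating-point digit; results are
cached per margin triple `(n1, n2, K)`, which makes genome-scale batches
cheap because sequencing depths repeat. Multiple testing is controlled by
Bonferroni over `m` = the number of *testable* SNPs — SNPs with zero depth
in either pool, which have no defined test, are excluded from `m`. The
adjusted value `p_adj = min(1, m·p)` is the quantity thresholded
everywhere in the reads arm (at 0.05, with stricter tiers 10⁻³ and 10⁻⁴
inside the cascade); some field usage calls this quantity an "FDR", but it
is a family-wise bound, and the package names it `p_adj`.

**Filtering cascade.** Five nested stages: (a) `p_adj < 0.05`; (b) stage
(a) inside annotated genes; (c) stage (b) restricted to missense SNPs;
(d) stage (c) at `p_adj < 10⁻⁴`; (e) genes carrying ≥1 SNP at
`p_adj < 10⁻³`. All four thresholds are configuration values with these
defaults. Genes with ≥2 differential SNPs are tallied separately.

**Dosage-array arm.** Each individual's five-class call contributes 4
chromosomes, so a group of `n` individuals yields allele counts
`(Σd, 4n−Σd)`. The 2×2 table is tested with Pearson's goodness-of-fit
chi-square, 1 df, no continuity correction; monomorphic SNPs get p = 1.
Treating the 4 chromosomes of one individual as independent ignores
within-individual dependence (double reduction, genotyping error
correlation); this mildly anti-conservative simplification is a documented
limitation of the allele-frequency framing.

**Effect classification.** A SNP enters the profile table when it passes
the arm's primary threshold for ≥1 trait (reads: `p_adj < 0.05`; array:
`p < 0.01`); the other traits are then flagged at the secondary threshold
(reads: `p_adj < 0.05`; array: `p < 0.05`). Direction is the sign of the
case-minus-control alt-frequency difference. Patterns: *antagonistic* when
TSC and TY directions are nonzero and opposite — or, when TY is absent
from the combination, TSC versus TSY (TSY is yield-weighted, so a
starch-up/starch-yield-down profile implies yield pulled the product
down); *unidirectional* when all nonzero directions agree (neutral
allowed; single-trait SNPs fall here by convention); *mixed* otherwise.
"Neutral" is operationalized as not significant at the secondary
threshold. Note the TSC/TSY fallback deliberately breaks exact TSC↔TY
relabel symmetry; with both core traits present the classification is
symmetric.

## Physical map and co-localization

Windows of 0.5 Mbp are anchored at position 1 of each chromosome (no
sliding grids); a gene is assigned to exactly one window by its start
coordinate (start rather than midpoint: deterministic and consistent with
how VCF/GFF order features). Peaks are maximal runs of strictly adjacent
windows with `gene_count ≥ min_genes` (default 3); width is not capped —
runs wider than 4 Mbp, beyond the expected LD scale, are reported with a
warning. Prominent peaks have ≥ `threshold` (default 10) genes in their
densest window.

Hit sets from different experiments are compared at three resolutions:
identical SNPs (strict chrom+pos+ref+alt match, preventing spurious
identity between arms), identical genes, and physical proximity (distance
from a hit to the nearest peak *interval*, 0 inside, co-localized when
strictly below 0.5 Mbp). QTL regions are single-linkage clusters of hits
(link distance 0.5 Mbp, transitive) that contain hits from ≥2 experiments;
a region spans its extreme hits, padded symmetrically to ≥1 Mbp but never
into a neighbouring region (padding is trimmed at the midpoint of the raw
gap), and regions wider than 4 Mbp are flagged. The exact region-delimiting
rule used in field studies is rarely algorithmic; this construction is a
principled, parameterized stand-in.

## Kinship mixed-model GWAS

Model: `y = Xb + u + e`, `u ~ N(0, σ²g K)`, `e ~ N(0, σ²e I)`, dosage as an
additive 0–4 predictor (no tetraploid dominance parameterization). `K` is
the VanRaden construction generalized to ploidy 4: markers centered by
mean dosage, cross-product normalized by `Σ 4 p̂(1−p̂)`; a marker subset
"for equal distribution" is chosen by equally spaced ranks per chromosome
(241 by default). Monomorphic-only subsets are rejected; `K` must be
symmetric and PSD within 1e-8 (eigenvalues clipped at 0 past that check).

Fitting is the eigendecomposition ("population parameters previously
determined") approximation: `K = U Λ Uᵀ` once; the variance ratio
`δ = σ²e/σ²g` is estimated on the null (intercept-only) model by profiled
maximum likelihood over a 61-point log₁₀ grid on [−5, 5] refined by
golden-section search (tolerance 1e-4 in log space); each SNP is then a
2-parameter weighted least-squares fit in the rotated space with weights
`1/(λᵢ+δ)`, closed-form 2×2 normal equations, and a Wald t-test on
`n−2` degrees of freedom. δ is reused across SNPs rather than re-estimated
per SNP — the standard fast approximation; with `K = I` the scan reduces
exactly to ordinary least squares (weights become constant), which is the
identity check in the tests. SNPs with zero dosage variance are untestable
(p = 1, no standard error). Population-structure covariates are not
modelled separately; the kinship random effect carries that burden (an
optional covariate matrix would be the natural extension). Calibration is
monitored by λ = median(χ²)/0.45494.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes:

* **Genome/annotation** — 12 chromosomes of 60–90 Mbp (≈849 Mbp total) by
  default; non-overlapping genes of 2–8 kbp placed uniformly (an optional
  U-shaped mode mimics gene-poor pericentromeric regions); 30% of SNPs are
  placed inside gene spans (sequenced SNP panels are enriched in genic
  space), and a genic SNP is exonic with probability 0.4, then missense
  with probability 0.5.
* **Population** — each individual is 4 haplotypes, each a block mosaic of
  a founder panel (24 haplotypes by default); block lengths are uniform on
  0.6–2.5 Mbp, the reported LD decay scale for euchromatic regions of
  tetraploid potato panels. Founder allele frequencies are uniform on
  [0.1, 0.9]; QTL sites are forced to frequency 1/2 in the founder panel so
  planted effects always segregate.
* **Phenotypes** — additive: `TSC = μ + Σ a_q d_q + e`, Gaussian noise
  rescaled against the *realized* genetic variance so the realized
  narrow-sense heritability matches the target (defaults h²(TSC)=0.7,
  h²(TY)=0.4, reflecting that yield is the less heritable trait);
  `TSY = TY·TSC/100` exactly (percent × yield keeps yield units). Baselines
  μ(TSC)=17%, μ(TY)=450 dt/ha.
* **Observation layers** — pooled read counts are Poisson(depth) per SNP
  with Binomial(depth, pooled alt frequency) alt reads (depth defaults to
  40× per pool per SNP; the true per-pool depth of any given study is not
  knowable from published summaries, so it is freely configurable);
  five-class dosage calls are perturbed ±1 class with a configurable error
  rate (default 2%), clamped to [0, 4].

What it does **not** emulate — and therefore what passing tests do not
show about real data: reference-bias and mapping artefacts in read counts
(depth is Poisson, not overdispersed, though an overdispersed layer would
be a one-line change), genotype-calling error structure of real array
intensity data, population structure beyond the founder-panel/family
devices, epistasis, G×E, and — importantly — realistic *local LD among the
founder haplotypes themselves*. In the block-mosaic model the expected r²
between a QTL and a neighbouring SNP is ≈ 1/(number of founders) ≈ 0.04,
so planted QTL are tagged essentially only by themselves; real panels show
massive redundancy (thousands of SNPs echoing one QTL), which is why the
published gene counts of pooled studies are orders of magnitude larger
than anything a desk-scale simulation reproduces.

## Problem sizes used in tests and the acceptance script

Simulations are scaled so the whole suite runs in minutes on one CPU, as a
design choice documented here: the Fisher oracle sweep covers all ~7.4×10⁵
tables with group totals ≤ 40; the null family-wise-error study uses 50
populations of 90 individuals, 20,000 SNPs, pools 24/24, depth 40×; QTL
recovery plants 5 equal-effect missense QTL (h²(TSC)=0.95) in populations
of 2,000 with 2,000 SNPs, 20 replicates; classification uses 4 planted QTL
in populations of 300 over 5 replicates per scenario (array arm);
mixed-model checks use 184 individuals in 8 founder-disjoint families with
2,000 SNPs; the CLI determinism chain uses a 2-chromosome 16-Mbp genome.
The scenario sizes were fixed by power analysis before the checks were
run: e.g. selecting 24 of 2,000 individuals (selection intensity i≈2.6) on
a trait with five equal QTL at h²=0.95 gives an expected pooled
allele-frequency shift of ≈0.55 per QTL, hence Fisher z ≈ 5–6 against a
Bonferroni threshold of z ≈ 4.2 at m = 2,000.

## Known limitations

* The pooled design itself does not control family-wise error at
  genome-wide scale: pools of 24 tetraploids contribute genetic sampling
  variance 2pq/96 to the frequency difference on top of the read sampling
  pq/depth the Fisher test models (~40% extra variance at 40×). Under a
  faithful no-QTL simulation roughly a third to a half of replicates show
  at least one Bonferroni-significant SNP — the genome-wide "background
  noise" any pooled case-control study must validate away; the
  corresponding acceptance test documents this by failing. Feeding the
  same machinery reads drawn from identical pool frequencies restores
  nominal control, which isolates the cause in the design, not the test.
* Bonferroni over several hundred thousand correlated SNPs is severely
  conservative in the other direction for true effects; the cascade's
  tiered thresholds are pragmatic, not optimal.
* The array arm's 4-chromosomes-per-individual counting ignores
  within-individual dependence (see above).
* `select_pools` assumes the adjusted means are exchangeable across
  genotypes; no weighting by phenotyping precision is attempted.
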