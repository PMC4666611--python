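# Methods

`isletqtl` implements an exon-level *cis*-eQTL mapping pipeline for bulk
RNA-seq cohorts (the motivating tissue is the human pancreatic islet) and
the downstream machinery that connects eQTL signals to GWAS loci: adaptive
permutation FDR, LD- and conditional-analysis colocalization, chromatin-state
overlap and enrichment, replication-rate (π1) estimation, and allele-specific
expression testing. Because the kind of donor cohort this targets is access
controlled, the package ships a synthetic-study generator with planted
truth; every statistical claim in the test suite is made against that truth
or against an exact enumeration oracle.

## Genotype QC

Variant filtering is two-stage, mirroring a genotype-then-impute design:

* directly genotyped variants must have call rate ≥ 0.99, MAF ≥ 0.01 and an
  exact Hardy–Weinberg p ≥ 1e-4;
* all variants entering the analysis must have imputation INFO > 0.4 and
  MAF > 0.05.

The HWE test enumerates the conditional distribution of the heterozygote
count given the allele counts (log-space recurrence-free enumeration) and
sums all configurations no more probable than the observed one. Dosages are
rounded to hard calls for HWE only; regression always uses unrounded
dosages. Missing dosages surviving QC are mean-imputed, which keeps each
variant's allele frequency — and therefore the regression design mean —
unchanged. Samples need ≥ 10 million exon-mapped reads.

## Expression phenotype

The scan phenotype is built per exon as

1. drop exons with zero counts in ≥ 10 samples (a fraction-based
   alternative, non-zero in ≥ 10% of samples, is selectable — the two rules
   differ and both are exposed rather than merged);
2. scale each sample's counts to the median per-sample total;
3. log2(x + 1) — the pseudocount is needed because zeros survive the filter;
4. rank-based inverse-normal transform Φ⁻¹((r − 0.5)/n) with average ranks
   on ties.

Step 4 makes each exon row carry exactly the normal-score multiset, so
per-exon effects are expressed on a standard-normal scale. A consequence
worth stating: if the latent expression signal is β·g + ε, the transform
rescales the recovered effect to roughly β/sd(β·g + ε). With the default
generator settings (residual SD 1, MAF 0.3) a planted β = 1 is recovered
around 0.77–0.84, not 1.0; the recovery tolerances in the tests account for
this known standardization shrinkage.

Hidden structure (donor characteristics, isolation center, storage,
purity) is captured by a deterministic factor-analysis stand-in: the top-k
left singular vectors of the per-exon-centered sample × exon matrix
(default k = 15, orthonormal across samples). This is a deliberate design
choice over a Bayesian factor model: the pipeline's contract is "regress out
k latent covariates", and the SVD version is dependency-free and bitwise
reproducible. A sex indicator is always appended as an additional covariate;
a factor-vs-sex correlation screen is emitted as a diagnostic only.

RPKM is computed as count / (exon kb) / (sample total in millions); values
below 0.1 are called "not expressed" (the boundary itself, 0.1, counts as
expressed).

## cis scan

For each gene the TSS is the annotated start (+ strand) or end (− strand);
the cis window is the closed interval TSS ± 1 Mb (clipped at position 1).
Every non-constant in-window variant is fit by OLS of the exon phenotype on
[1, dosage, covariates] with a two-sided t-test on the dosage term. The
implementation projects the covariates out of phenotype and dosages once per
exon (Frisch–Waugh) and computes all per-variant statistics vectorized; this
is algebraically identical to the joint fit and is verified against both a
normal-equations oracle and statsmodels in the tests. The index variant is
the smallest p, ties broken by larger |t| then smaller position.

## Adaptive permutation and FDR

The per-exon multiple-testing correction permutes the genotype rows only —
expression and covariates stay paired — and rescans the full window for the
permuted minimum p. Batches of 1,000 permutations run until at least 1,000
permutations are done and at least 15 permuted minima beat the observed one,
with a hard stop at 10,000; the empirical p is (r + 1)/(n + 1).

Two implementation notes:

* permuted and observed fits share their residual degrees of freedom, so
  "permuted min p ≤ observed min p" is equivalent to "permuted max partial
  r² ≥ observed max partial r²"; the inner loop compares r² and never
  evaluates p-values;
* permuting the genotype rows by π is the same regression as permuting the
  (residual phenotype, covariate basis) rows by π⁻¹, which turns a batch of
  permutations into one batched matrix product. The equivalence with a
  literal per-permutation re-fit is asserted in the tests.

Permutation streams are exon-indexed children of the master seed, so a rerun
reproduces every exon's empirical p regardless of scan order.

Empirical p-values across exons enter a Storey q-value computation: π̂0 from
the λ-grid {0.05, …, 0.95} with a cubic least-squares smoother evaluated at
λ = 0.95, clamped to [1/m, 1]; below 100 p-values a fixed λ = 0.5 is used
with a warning. q-values follow the step-up rule q(p(i)) = min over j ≥ i of
π̂0·m·p(j)/j. Tiers: study-wide q < 0.05; nominal, empirical p < 0.05.

π1 = 1 − π̂0 of a replication p-value vector estimates the replication rate.
π1 is conservative for heavy-tailed alternatives: for a Beta(0.1, 1)
alternative the estimator's ceiling is π1_true − π1_true·P(p > 0.95)/0.05 ≈
0.63 when π1_true = 0.70, and the tests assert that computable ceiling
rather than pretending the estimator is unbiased there. For light-tailed,
replication-style alternatives (two-sided p-values of |z| ~ N(3, 1)) the
70% rate is recovered within ±0.05.

## GWAS effector nomination

Per GWAS locus and per gene with TSS within 1 Mb of the lead variant, the
gene's best exon (smallest empirical p; ties by q, then TSS) must pass:

1. tier: study-wide (q < 0.05) or nominal (empirical p < 0.05);
2. LD: r²(index variant, lead) > 0.8, computed from the analysis cohort's
   own dosages (an external reference panel is deliberately not required —
   the cohort r² is what the conditional model actually uses);
3. conditional analysis: adding the lead dosage to the model must remove
   the index variant's signal (conditional p > 0.05 by default; the
   alternative "≥ 90% drop in −log10 p" statistic is computed and reported
   alongside). Index/lead pairs with r² > 0.999 are flagged collinear and
   treated as fully absorbed (conditional p = 1);
4. chromatin: the index variant or any r² > 0.8 proxy must overlap an
   active (enhancer/promoter) state in at least one annotation dataset.

Surviving calls carry the expression direction oriented to the risk allele
(β is per alt-allele dose; the sign flips if the risk allele is the
reference allele — the report is invariant to ref/alt relabeling) and a
directional-consistency count: of the gene's exons, how many share the sign
of the index exon's β at the index variant, formatted "23/24"-style.

**Known limitation — winner's curse in the conditional gate.** The index
variant is chosen by min-p selection over the window. When a strong-LD proxy
of the true causal variant wins by chance, the same noise alignment that
made it win inflates its conditional signal given the lead, and the strict
conditional p > 0.05 rule then rejects a genuinely shared locus. With 50
exchangeable r² ≈ 0.9 proxies, planted β = 1 and n = 150–200, the measured
per-replicate probability that a shared-causal locus survives the whole
cascade is roughly 0.6–0.8, while the conditional rule evaluated on the
causal variant or a pre-specified proxy passes ≥ 90% (see the acceptance
tests for both measurements). Loci failing only this gate still show a
large −log10 p drop, which is why the depletion statistic is reported next
to the hard threshold.

## Chromatin overlap and enrichment

Variants are 1-based points, BED intervals 0-based half-open; a variant at
position p overlaps [s, e) iff s < p ≤ e. Overlap is the union over
requested states and datasets ("active in at least one map"); per-dataset
flags and an "any annotation" indicator (for the restricted, annotated-only
overlap rate) are available. Enrichment of the significant index variants
against the non-significant background is tested two ways: Fisher's exact
test on the 2 × 2 overlap table (two-sided, with both one-sided values
reported) and 10,000 resamplings of foreground-sized draws from the
background without replacement, p = (exceedances + 1)/(n + 1). No MAF or
TSS-distance matching is applied to the background by default.

## Allele-specific expression

Per heterozygous carrier with coverage ≥ 10 reads the statistic is the alt
fraction minus 0.5; zero differences are dropped (classical convention) and
the rest enter a two-sided Wilcoxon signed-rank test. For n ≤ 25 the exact
null distribution is built by dynamic programming over doubled (half-integer
safe) average ranks — exact even under ties, verified against full 2ⁿ sign
enumeration; above 25 a normal approximation with continuity and tie
corrections is used. The test is invariant to swapping ref/alt labels.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
human genome realism (no recombination maps, no population structure, no
realistic gene models):

* **Genotypes.** Each LD block draws a latent founder haplotype pair
  (Bernoulli(MAF) per haplotype); every emitted variant copies the founder
  allele and refreshes it with switch probability s = 1 − target_r2^(1/4),
  giving every emitted pair r² ≈ target. Dosages are haplotype sums, hence
  Hardy–Weinberg. target_r2 = 1 yields exact copies. The founder itself is
  not emitted; emitting it would make the pairwise r² distribution bimodal.
* **Expression.** Latent per-exon signal β·dosage + loadings·factors +
  Gaussian noise (defaults: 15 factors, factor SD 0.5, noise SD 1, matching
  a cohort where technical structure dominates); counts are Poisson with
  mean proportional to a lognormal base abundance × 2^latent × library
  size, with a *fixed* normalizing denominator — normalizing by the realized
  per-sample sum would cancel planted effects compositionally. Library
  sizes are uniform on 29–165 million reads, the depth range the pipeline's
  sample filter is calibrated against. Negative-binomial overdispersion is
  intentionally omitted: the rank-normal transform makes the count law
  secondary. Two generator artifacts are worth knowing: depth
  renormalization of convex count means creates a |factor|-shaped technical
  component (it shows up as an extra inferred factor), and a planted gene's
  recovery tests need enough decoy exons that the per-sample totals are not
  driven by the planted gene itself.
* **GWAS loci.** A shared-causal locus reports the planted eQTL variant
  itself as the lead ("exact sharing"; a best-proxy mode exists). This is a
  deliberate definition: a lead at r² ≈ 0.95 to the causal variant retains
  residual conditional signal (non-centrality ≈ β·sqrt(n·var(g)·(1 − r²)))
  and would fail the p > 0.05 elimination rule half the time, which would
  test the simulator, not the method. Independent loci draw a lead with
  r² < 0.05 to every planted variant.
* **Chromatin.** Active-state intervals cover planted variants at fold ×
  background rate and others at background rate; "quiescent" intervals and
  a two-dataset split exercise state filtering and the annotated-only
  denominator. A `guarantee_planted` switch covers every planted variant
  deterministically for end-to-end tests whose subject is the nomination
  logic rather than these coin flips.
* **ASE.** Alt counts are Binomial(depth, allelic fraction) per carrier.

All randomness descends from one master seed through named child streams
(genotypes / expression / GWAS / chromatin / ASE), so identical configs are
bitwise reproducible; the pipeline's permutation streams are additionally
exon-indexed.

What passing on synthetic data does **not** show: robustness to realistic
LD decay, rare variants, overdispersed counts beyond the rank-normal
safety net, cell-type composition shifts, or reference-panel/LD mismatch —
none of which the generator emulates.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use study sizes chosen to make
every stochastic bound comfortably measurable at desk scale: 200 samples,
200 exons and 50-variant windows for calibration/FDR (20 replicates for the
FDR bound), 100 replicates for index-variant recovery, 2,000 foreground
variants over a 6,000-variant panel for enrichment, m = 5,000 for π1.
Window bounds are closed; positions 1-based; the RPKM expressed boundary is
closed at 0.1; empirical and resampling p-values use the +1 pseudo-count;
collinearity tolerance r² > 0.999; covariate bases are rejected when rank
deficient rather than silently dropped. DS fields read from VCF are rounded
to 6 decimals to undo float32 transport noise.
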