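# Methods

This note documents the models implemented in `gatescores`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic-data
generator does and does not emulate.

## Locus construction

Summary statistics (per gene × SNP univariate regression coefficients of
expression on dose) are filtered at `snp_p_threshold` (default 10⁻⁵) at read
time.  Clumping is **single-linkage by position**: per chromosome, a new
chunk starts whenever the gap to the previous retained SNP is
≥ `clump_gap` (default 1 Mb exactly, i.e. 1 000 000 bp with 1-based
positions); chunks without an index SNP at `index_p_threshold` (default
10⁻⁶, strict inequality) are discarded.  Single-linkage is the simplest rule
under which the resulting chunks are "separated by at least 1 Mb", and for
sorted positions a single pass and iterative merging give identical
partitions.  The cis/trans call anchors the distance at the **nearest SNP in
the chunk** to the transcription site (the chunk has no other natural anchor
point); cis means same chromosome and distance ≤ `cis_window` (5 Mb).
Trans loci overlapping `hla_chrom:hla_start–hla_end` (default chr 6:
25–34 Mb) are removed before aggregation for every gene — the HLA region is
a trans-QTL hotspot for immune genes whose disease associations are
confounded by direct HLA effects.  The interval is configurable and
deliberately genome-build-agnostic: nothing in the pipeline depends on a
particular build, and users should set the interval for theirs.

## LD adjustment

Let *b* be the univariate betas of a locus, *R* the SNP-dose correlation
matrix and *S* the diagonal of dose SDs, both from the reference panel.
Weights solve the system on the per-SD scale:

    w = S⁻¹ [(1−λ)R + λI]⁻¹ S b .

With λ = 0 this equals Σ⁻¹c (Σ the dose covariance, c the dose–expression
covariances), i.e. the OLS multiple-regression coefficients when the panel
is the QTL-study sample itself — asserted to < 10⁻⁸ in the tests.  The
shrinkage λ = `ld_shrinkage` (default 0.1) guarantees invertibility with
small panels; tests that assert exactness use λ = 0.  A condition number
above 10¹² raises an error suggesting larger λ.  Allele harmonization
matches SNPs by (chromosome, position); swapped alleles flip the sign of
beta (and the dosage orientation at scoring time); strand-ambiguous (A/T,
C/G) or inconsistent allele pairs are dropped with a warning — the
conservative standard when strand information is absent.

## Scores and the diversity index

The locus score is the dot product of effect-allele doses with the weights;
missing dosages are mean-imputed per SNP **at score time**, never at read
time, so missingness is preserved in the stored data.  Trans locus scores
are summed (unweighted) into the GATE score; cis scores are summed
separately and never enter the trans aggregate.  Variances use denominator
n−1 and are computed **in the target cohort** — that is where the scores
exist; the reference panel only supplies LD.  The effective number of
unlinked trans-QTLs is the Hill number

    2^(−Σ pᵢ log₂ pᵢ),   pᵢ = σᵢ²/Σσⱼ²,

with the continuity convention 0·log₂0 := 0 (unit-tested).  It is scale
invariant, Schur-concave, equals 1 when a single locus dominates and K for
equal variances.

## Efficient-score association testing

One null logistic regression of the binary phenotype on covariates (with
intercept) is fitted per cohort (statsmodels IRLS, tolerance 10⁻⁸, max 50
iterations); samples in the cohort's exclusion set are removed first.
Rank-deficient covariates raise an error naming the collinear columns;
fitted probabilities within 10⁻¹⁰ of 0/1 raise a quasi-separation error.
For a score vector *g*:

    U = gᵀ(y − μ̂),   V = gᵀWg − gᵀWC(CᵀWC)⁻¹CᵀWg,   W = diag(μ̂(1−μ̂)).

z = U/√V is referred to N(0,1) two-sidedly (sidedness is a design choice;
the score's direction is not privileged).  The log odds ratio is the
one-step estimator β = U/V — the first Newton step from the null,
asymptotically equivalent to the MLE for small effects, which is the regime
GATE scores live in — and is reported per SD of the score
(β·SD(g)), making it invariant to affine rescaling of the raw score.
V ≤ 10⁻¹² flags the score as untestable (it lies in the covariate span).
The normal approximation is used without small-sample correction; with case
fractions below ~1% users should treat extreme tails with caution (the
docstring flags this).

Candidate filtering uses fixed thresholds rather than FDR because the
hypothesis space is effectively the number of genes with a computable
diverse GATE score, not the number of SNPs: pass iff effective trans-QTLs
> `min_effective_trans` (5) and trans-score *P* < 10⁻⁵, or *P* < 10⁻⁴ with a
catalogued GWAS hit within 200 kb of the TSS.  The filter is idempotent and
order-independent.

Shared trans-QTL structure: Pearson correlations of candidate GATE scores
are reordered by average-linkage hierarchical clustering on 1−|r| (average
linkage is the choice where only "clustering on the absolute correlation"
is specified); |r| > 0.8 components are flagged as shared-QTL groups.
Trans clumps of candidate genes are merged transitively on interval overlap
per chromosome and tabulated with target genes and genes whose TSS falls in
the merged interval.

Per-locus disease effects (the MR outcome side) reuse the same score test
on individual locus scores — the natural within-framework choice for
obtaining per-instrument effects.

## Mendelian randomization

Instruments are a gene's trans loci: x_j is the locus effect on expression
per SD of the locus score, computed as Ĉov(score, expression)/SD(score)
with the covariance implied by the univariate summary betas
(Σ w_k b_k Var(d_k)); this makes x_j invariant to rescaling of the weight
vector.  y_j is the one-step log OR per SD of the locus score with SE
SD/√V.  Genes with fewer than `mr_min_instruments` (10) trans-QTLs are
skipped: the power of the dose-response test depends critically on the
instrument count.

The likelihood of the causal effect θ marginalizes unobserved direct
effects with a spike-and-slab mixture, exactly (closed form per
instrument):

    L(θ) = Σ_{π,τ} prior(π,τ) Π_j [(1−π)·N(y_j; θx_j, s_j²) + π·N(y_j; θx_j, s_j² + τ²)]

with a uniform prior over π ∈ {0, 0.1, …, 0.9} and half-normal weights
(scale SD(y)) over 8 log-spaced τ from 0.01 to 2·SD(y).  Direct numerical
marginalization over this grid was chosen over MCMC because the mixture is
exact, fast and fully testable; with π ≡ 0 it reduces to weighted least
squares and the MLE equals the IVW estimate (asserted to grid resolution).
θ is profiled on a 401-point grid centered on the IVW estimate spanning
±5× the ratio-estimate spread (always covering 0), with parabolic
refinement at the maximum; the likelihood at θ = 0 is evaluated exactly.
lr = 2(ℓ(θ̂) − ℓ(0)) is referred to χ²(1).  The exposure-side error s_x is
recorded but not propagated (fixed-x approximation, standard in two-sample
MR when the QTL study is large); a warning is logged when
max s_x/|x| > 0.2.  A caveat is inherent to the design and reported in the
module documentation: instruments coupled to disease through a shared
pathway yield causal-pathway rather than gene-level inference, and the test
cannot distinguish the two.

## Synthetic-data generator

Genotypes are Gaussian-copula thresholded: per LD block, each gamete is a
latent MVN with correlation ρ^|i−j| (default ρ = 0.6), a SNP's allele
indicator is the latent value below the Φ⁻¹(MAF) quantile, and the dose is
the gamete sum — preserving exactly the properties the pipeline consumes
(MAF, local LD, Hardy–Weinberg doses) at trivial cost compared with
coalescent simulation.  MAFs are uniform on [0.05, 0.5], fixed by the
architecture seed so all cohorts share them.  Blocks are anchored 3 Mb
apart (beyond the clump gap, so each block clumps on its own) with SNPs
5 kb apart.

The default architecture plants one core gene with 8 trans loci (3 SNPs
each) on 6 chromosomes, one extra trans locus inside the HLA interval, and
one cis SNP at the TSS; per-locus genetic variance is 0.056 so the trans
heritability of expression is ≈ 0.3 of total (with noise SD 1 and cis
variance 0.05) — the realistic whole-blood regime where trans effects carry
most of the heritable signal.  Two decoy genes carry the same style of
trans architecture on disjoint blocks but no disease effect.  Disease risk
is logistic with intercept log(1/9) (background prevalence 0.1 — large
enough that desk-scale cohorts contain cases), log OR 0.3 per SD of core
expression, covariate effects (0.25 on a binary sex-like covariate, 0.1 on
three standard-normal components), and optional direct SNP effects.  The
QTL study (default n = 5 000), reference panel (n = 2 000) and target
cohort (n = 20 000) are independent draws.

What the generator does **not** emulate: realistic human LD maps and MAF
spectra, population structure and relatedness, imputation uncertainty,
cross-chromosome LD, and the extreme case imbalance of biobank cohorts.
Passing tests therefore demonstrate the statistical machinery — clumping,
LD adjustment, calibration, recovery, pleiotropy robustness — under the
assumed generative structure, not performance on real biobank data.

## Problem sizes used in the tests

The acceptance suite runs the analytic checks at the sizes stated in their
docstrings (LD oracle n = 2 000 × 10 SNPs; calibration 5 000 null scores at
n = 5 000; Wald equivalence n = 20 000; end-to-end recovery 100 seeds at
n_gwas = 5 000, n_cohort = 20 000; MR 200 + 500 replicates at K = 20).
Unit tests use smaller draws of the same generators; sizes there are chosen
so each statistical assertion has comfortable margin at a fixed seed.

## Known limitations

* No relatedness- or mixed-model-aware association; the cohort is assumed
  unrelated (the generator produces unrelated individuals).
* Fixed-threshold candidate filtering only; no FDR machinery.
* No conditional fine-mapping inside a locus, and no BGEN/PLINK binary
  genotype formats (VCF or dosage-matrix TSV only).
* The MR grids are adequate for the effect sizes the pipeline produces;
  pathological instrument sets (all x ≈ 0) are flagged untestable rather
  than extrapolated.
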