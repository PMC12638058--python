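# gatescores

Genome-wide aggregated *trans*-effects (GATE) analysis: a Python library for
finding **core genes** of complex diseases from QTL summary statistics.

## The scientific problem

The omnigenic ("sparse effector") model holds that most polygenic effects on
a complex trait are mediated by many weak *trans*-effects of common variants
that coalesce on the expression of a small set of core effector genes.
Because such genes are depleted of large-effect *cis*-eQTLs, they are hard to
find by SNP-by-SNP GWAS.  GATE analysis attacks the problem from the other
side: it aggregates a gene's *trans*-QTL effects, taken from an external
expression or protein GWAS, into a per-individual genotypic predictor of
that gene's expression, and tests the predictor against disease in a target
cohort.  The package is aimed at statistical geneticists with access to QTL
summary statistics, an LD reference panel and an individual-level
case-control cohort.

## The method

1. **Loci.** Per gene, summary statistics are filtered at *P* < 10⁻⁵; maximal
   chunks of retained SNPs separated by ≥ 1 Mb form clumps, kept as QTL loci
   only if they contain an index SNP at *P* < 10⁻⁶.  A locus is *cis* if it
   lies within 5 Mb of the gene's transcription site (same chromosome),
   *trans* otherwise; trans loci overlapping the HLA interval
   (chr 6: 25–34 Mb) are excluded from aggregation.
2. **Weights.** Univariate coefficients *b* are corrected for LD with a
   reference-panel SNP correlation matrix *R*:
   on the per-SD scale, *w* = ((1−λ)R + λI)⁻¹ *b*, approximating the
   multiple-regression coefficients (exactly, when λ = 0 and the panel is the
   QTL-study sample).
3. **Scores.** Each individual's locus score is the dot product of dosages
   and weights; trans locus scores are summed into the gene's GATE score,
   cis scores are kept separate.  The effective number of unlinked
   trans-QTLs is the Hill number 2^(−Σ pᵢ log₂ pᵢ), pᵢ = σᵢ²/Σσⱼ², of the
   locus-score variances.
4. **Association.** One null logistic regression of disease on covariates is
   fitted; each score is tested with the efficient score statistic
   U = gᵀ(y−μ̂), V = gᵀWg − gᵀWC(CᵀWC)⁻¹CᵀWg, reported as a standardized
   log odds ratio (per SD of score).  Candidates must have effective
   trans-QTLs > 5 and *P* < 10⁻⁵ (or *P* < 10⁻⁴ with a known GWAS hit within
   200 kb of the TSS).
5. **Shared structure & causality.** Candidate GATE scores are clustered on
   1−|r| to expose genes regulated by the same trans-QTLs; overlapping
   clumps are merged and tabulated.  For genes with ≥ 10 trans-QTLs, a
   dose-response (Mendelian-randomization) test profiles the marginal
   likelihood of the causal effect θ, marginalizing direct instrument
   effects over a spike-and-slab mixture so that balanced pleiotropy does
   not bias θ̂.

A bundled generator (`gatescores.synthetic_data`) produces LD-blocked
genotypes, omnigenic expression, summary statistics and case-control cohorts
so that the full pipeline runs and is tested without restricted data.

## Worked example

`python examples/02_gate_association_pipeline.py` simulates the default
planted architecture (one core gene raising disease risk with log OR 0.3 per
SD of expression, two decoy genes; n_gwas = 5 000, n_cohort = 20 000) and
runs the full pipeline.  It prints:

```
gene_id symbol chrom  tss_mb  gwas_hit_within_200kb  effective_n_trans  trans_logOR      trans_p  cis_logOR    cis_p
  CORE1  CORE1     1    3.02                  False           7.770500     0.144019 6.085595e-11   0.042206 0.055239
 DECOY1 DECOY1     3    9.02                   True           7.945215     0.000916 9.668279e-01   0.005891 0.789377
 DECOY2 DECOY2     7   21.02                  False           7.960636     0.001758 9.363836e-01        NaN      NaN

gene_id  effective_n_trans         pval  passed    reason
  CORE1           7.770500 6.085595e-11    True primary_p
 DECOY1           7.945215 9.668279e-01   False        ns
 DECOY2           7.960636 9.363836e-01   False        ns
```

The core gene is recovered with a positive standardized log OR at
*P* ≈ 6×10⁻¹¹ and an effective trans-QTL count of ~7.8 (8 unlinked planted
loci; the planted HLA-interval locus is excluded and the cis locus tested
separately), while both decoys are null and fail the filter.  The other
examples cover bundle generation (`01`), the Hill number and shared-QTL
blocks (`03`), and pleiotropy-robust MR (`04`).

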