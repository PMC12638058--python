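"""Shared fixtures: tiny synthetic cohorts and helper constructors."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gatescores import (CohortData, GeneAnnotation, PipelineConfig,
                        SummaryStatRecord)
from gatescores.qtl_loci import QtlLocus


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


def make_record(gene_id="G1", chrom="1", pos=1_000_000, beta=0.1, se=0.02,
                pval=1e-7, n=5000, effect_allele="A", other_allele="G"):
    return SummaryStatRecord(gene_id=gene_id, chrom=chrom, pos=pos,
                             effect_allele=effect_allele, other_allele=other_allele,
                             beta=beta, se=se, pval=pval, n=n)


def make_locus(positions, betas=None, pvals=None, gene_id="G1", chrom="1",
               weights=None, locus_class="trans"):
    betas = betas if betas is not None else [0.1] * len(positions)
    pvals = pvals if pvals is not None else [1e-8] * len(positions)
    snps = [make_record(gene_id=gene_id, chrom=chrom, pos=p, beta=b, pval=pv)
            for p, b, pv in zip(positions, betas, pvals)]
    return QtlLocus(gene_id=gene_id, chrom=chrom, start=min(positions),
                    end=max(positions), snps=snps, locus_class=locus_class,
                    weights=None if weights is None else np.asarray(weights, float))


def make_cohort(dosages, phenotype=None, covariates=None, chrom="1",
                positions=None, exclusions=()):
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    if positions is None:
        positions = [1_000_000 + 10_000 * j for j in range(p)]
    snp_map = pd.DataFrame({
        "chrom": [chrom] * p, "pos": positions,
        "effect_allele": ["A"] * p, "other_allele": ["G"] * p})
    if phenotype is None:
        phenotype = np.zeros(n, dtype=int)
        phenotype[: n // 2] = 1
    if covariates is None:
        covariates = np.ones((n, 1))
        names = ["intercept"]
    else:
        covariates = np.asarray(covariates, float)
        names = [f"c{j}" for j in range(covariates.shape[1])]
        names[0] = "intercept"
    return CohortData(sample_ids=[f"S{i}" for i in range(n)], dosages=dosages,
                      snp_map=snp_map, phenotype=np.asarray(phenotype),
                      covariates=covariates, covariate_names=names,
                      exclusions=set(exclusions))


def make_logistic_cohort(n, rng, n_cov=4, intercept=np.log(1 / 9),
                         cov_effects=(0.25, 0.1, 0.1, 0.1), score_effect=0.0,
                         score=None):
    """Cohort with a logistic phenotype on covariates (+ optional score)."""
    sex = rng.integers(0, 2, n).astype(float)
    others = rng.standard_normal((n, n_cov - 1))
    C = np.column_stack([np.ones(n), sex, others])
    eta = intercept + C[:, 1:] @ np.asarray(cov_effects[: n_cov], float)
    if score is not None:
        eta = eta + score_effect * score
    y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
    return make_cohort(np.zeros((n, 1)), phenotype=y, covariates=C), C


@pytest.fixture
def gene_g1() -> GeneAnnotation:
    return GeneAnnotation("G1", "G1", "1", 78_650_000)
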