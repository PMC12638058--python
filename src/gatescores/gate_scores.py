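"""Per-locus genotypic scores, GATE aggregation and the Hill diversity index.

The locus-specific score of an individual is the dot product of their
effect-allele doses with the LD-adjusted weight vector.  Locus scores are
summed over trans loci to give the gene's GATE (genome-wide aggregated
trans-effects) score; cis loci are summed separately and tested separately.

The effective number of unlinked trans-QTLs behind a GATE score is the Hill
number ``2 ** (-sum p_i log2 p_i)`` with ``p_i = sigma_i^2 / sum sigma_j^2``
computed from the cohort variances of the K locus-specific scores; it runs
from 1 (one locus dominates) to K (equal variances).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io_formats import CohortData, allele_orientation
from .qtl_loci import QtlLocus

logger = logging.getLogger("gatescores")


@dataclass
class LocusScore:
    """Per-sample score for one locus plus its cohort variance."""

    locus: QtlLocus | None
    values: np.ndarray
    variance: float
    expression_covariance: float = float("nan")  # Cov(score, predicted expression)
    dose_variances: np.ndarray | None = None     # cohort dose variances of used SNPs
    used_weights: np.ndarray | None = None
    used_ses: np.ndarray | None = None

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


@dataclass
class GateScore:
    """Aggregated trans score for one gene, with variance decomposition."""

    gene_id: str
    values: np.ndarray
    locus_variances: list[float]
    effective_n: float
    cis_values: np.ndarray | None = None

    @property
    def n_trans_loci(self) -> int:
        return len(self.locus_variances)


def match_locus_to_cohort(cohort: CohortData, locus: QtlLocus
                          ) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Align a weighted locus with cohort columns.

    Returns (dosage submatrix in effect-allele orientation of the locus,
    weight subvector, matched column indices).  Cohort SNPs with swapped
    alleles are re-oriented as ``2 - dose``; strand-ambiguous or inconsistent
    SNPs and SNPs absent from the cohort are dropped with a warning.
    """
    if locus.weights is None:
        raise ValueError("locus has no weights; run adjust_weights first")
    cols, flips, w, kept_idx = [], [], [], []
    for k, rec in enumerate(locus.snps):
        j = cohort.snp_column(rec.chrom, rec.pos)
        if j is None:
            logger.warning("locus SNP %s:%d absent from cohort; dropped", rec.chrom, rec.pos)
            continue
        orient = allele_orientation(rec.effect_allele, rec.other_allele,
                                    cohort.snp_map["effect_allele"].iat[j],
                                    cohort.snp_map["other_allele"].iat[j])
        if orient is None:
            logger.warning("locus SNP %s:%d ambiguous/inconsistent with cohort; dropped",
                           rec.chrom, rec.pos)
            continue
        cols.append(j)
        flips.append(orient)
        w.append(locus.weights[k])
        kept_idx.append(k)
    if not cols:
        raise ValueError(
            f"no SNPs of locus {locus.chrom}:{locus.start}-{locus.end} present in cohort")
    D = cohort.dosages[:, cols].copy()
    for c, f in enumerate(flips):
        if f < 0:
            D[:, c] = 2.0 - D[:, c]
    # per-SNP mean imputation of missing dosages at score time
    if np.isnan(D).any():
        mu = np.nanmean(D, axis=0)
        inds = np.where(np.isnan(D))
        D[inds] = np.take(mu, inds[1])
    return D, np.asarray(w, dtype=float), kept_idx


def locus_score(cohort: CohortData, locus: QtlLocus) -> LocusScore:
    """Dot product of each individual's doses with the adjusted weights."""
    D, w, kept_idx = match_locus_to_cohort(cohort, locus)
    values = D @ w
    variance = float(np.var(values, ddof=1)) if len(values) > 1 else 0.0
    # Cov(score, expression) implied by the univariate summary coefficients:
    # sum_k w_k * b_k * Var(dose_k), used for MR instrument scaling.
    var_d = (np.var(D, axis=0, ddof=1) if D.shape[0] > 1
             else np.zeros(D.shape[1]))
    betas = np.array([locus.snps[k].beta for k in kept_idx])
    ses = np.array([locus.snps[k].se for k in kept_idx])
    expr_cov = float(np.sum(w * betas * var_d))
    return LocusScore(locus=locus, values=values, variance=variance,
                      expression_covariance=expr_cov, dose_variances=var_d,
                      used_weights=w, used_ses=ses)


def diversity_index(variances: list[float] | np.ndarray) -> float:
    """Hill number of the variance shares: 2^(-sum p_i log2 p_i).

    ``p_i = sigma_i^2 / sum sigma_j^2`` with the continuity convention
    ``0 * log2(0) := 0``.  Equals 1 when one locus carries all variance and
    K when all K variances are equal.
    """
    v = np.asarray(variances, dtype=float)
    if v.size == 0 or np.any(v < 0):
        raise ValueError("variances must be nonnegative and nonempty")
    total = v.sum()
    if total <= 0:
        raise ValueError("all locus variances are zero; diversity undefined")
    p = v / total
    nz = p[p > 0]
    entropy_bits = float(-(nz * np.log2(nz)).sum())
    return float(2.0 ** entropy_bits)


def aggregate(gene_id: str,
              locus_scores: list[LocusScore],
              cis_scores: list[LocusScore] | None = None) -> GateScore | None:
    """Sum trans locus scores into the gene's GATE score.

    Cis locus scores are summed separately (never into the trans aggregate).
    Returns None, with a logged reason, when no trans loci contribute.
    """
    cis_scores = cis_scores or []
    if not locus_scores:
        logger.info("gene %s skipped: no trans loci contribute a GATE score", gene_id)
        return None
    lengths = {len(s.values) for s in locus_scores} | {len(s.values) for s in cis_scores}
    if len(lengths) != 1:
        raise ValueError(f"locus score lengths differ for gene {gene_id}: {sorted(lengths)}")
    values = np.sum([s.values for s in locus_scores], axis=0)
    variances = [s.variance for s in locus_scores]
    cis_values = (np.sum([s.values for s in cis_scores], axis=0)
                  if cis_scores else None)
    return GateScore(
        gene_id=gene_id,
        values=values,
        locus_variances=variances,
        effective_n=diversity_index(variances),
        cis_values=cis_values,
    )
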