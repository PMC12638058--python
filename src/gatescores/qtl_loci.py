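"""Clumping of QTL summary statistics into loci and LD adjustment of weights.

A *clump* (chunk) is a maximal run of retained SNPs on one chromosome in
which consecutive SNPs are separated by less than the clump gap (1 Mb by
default).  A clump is kept as a QTL locus only if it contains at least one
index SNP with P below the index threshold (1e-6).  Loci are classified cis
if the nearest SNP lies within the cis window (5 Mb) of the gene's
transcription site on the same chromosome, trans otherwise, and trans loci
overlapping the configured HLA interval are removed from genome-wide
aggregation.

The per-locus weight vector corrects the univariate summary coefficients for
linkage disequilibrium: on the per-SD (correlation) scale the weights are
``R_lambda^{-1} b_sd`` where ``R_lambda = (1 - lambda) R + lambda I`` is the
shrunken reference-panel SNP correlation matrix.  With ``lambda = 0`` and the
panel equal to the QTL-study sample this reproduces the multiple-regression
coefficients of expression on the locus SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (GeneAnnotation, PipelineConfig, SummaryStatRecord,
                         allele_orientation)

logger = logging.getLogger("gatescores")


@dataclass
class QtlLocus:
    """A clump of retained SNPs treated as one eQTL/pQTL."""

    gene_id: str
    chrom: str
    start: int
    end: int
    snps: list[SummaryStatRecord]
    locus_class: str | None = None  # "cis" or "trans"
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.snps:
            raise ValueError("a locus must contain at least one SNP")
        if len({s.chrom for s in self.snps}) != 1:
            raise ValueError("all SNPs in a locus must share one chromosome")
        if self.start > self.end:
            raise ValueError("locus start must be <= end")
        if self.weights is not None and len(self.weights) != len(self.snps):
            raise ValueError("weights length must equal number of SNPs")

    @property
    def min_pval(self) -> float:
        return min(s.pval for s in self.snps)

    @property
    def n_snps(self) -> int:
        return len(self.snps)


@dataclass
class LdReference:
    """Reference-panel dosages restricted to the SNPs of interest.

    Provides the SNP-dose correlation matrix and per-SNP dose standard
    deviations needed for LD adjustment.  ``from_correlation`` constructs a
    panel directly from a correlation matrix (unit SDs unless given), which
    is convenient for analytic tests.
    """

    dosages: np.ndarray | None
    snp_map: pd.DataFrame
    _R: np.ndarray | None = field(default=None, repr=False)
    _sds: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self._index = {
            (c, int(p)): j
            for j, (c, p) in enumerate(zip(self.snp_map["chrom"], self.snp_map["pos"]))
        }

    @classmethod
    def from_correlation(cls, R: np.ndarray, snp_map: pd.DataFrame,
                         sds: np.ndarray | None = None) -> "LdReference":
        R = np.asarray(R, dtype=float)
        if sds is None:
            sds = np.ones(R.shape[0])
        return cls(dosages=None, snp_map=snp_map, _R=R, _sds=np.asarray(sds, float))

    def snp_column(self, chrom: str, pos: int) -> int | None:
        return self._index.get((chrom, int(pos)))

    def correlation(self, cols: np.ndarray) -> np.ndarray:
        if self._R is not None:
            return self._R[np.ix_(cols, cols)]
        X = self.dosages[:, cols]
        if np.isnan(X).any():  # panels are expected complete; impute defensively
            mu = np.nanmean(X, axis=0)
            X = np.where(np.isnan(X), mu, X)
        with np.errstate(invalid="ignore"):
            R = np.corrcoef(X, rowvar=False)
        return np.atleast_2d(R)

    def dose_sds(self, cols: np.ndarray) -> np.ndarray:
        if self._sds is not None:
            return self._sds[cols]
        return np.nanstd(self.dosages[:, cols], axis=0, ddof=1)


# ---------------------------------------------------------------------------


def assign_clumps(records: list[SummaryStatRecord],
                  config: PipelineConfig) -> list[QtlLocus]:
    """Partition one gene's retained SNPs into QTL loci by the gap rule.

    Single-linkage by position: a new chunk starts whenever the gap to the
    previous retained SNP on the same chromosome is >= ``clump_gap``.  Chunks
    with no SNP at P < ``index_p_threshold`` (strict) are discarded.
    """
    if not records:
        return []
    genes = {r.gene_id for r in records}
    if len(genes) != 1:
        raise ValueError(f"assign_clumps expects records for one gene, got {sorted(genes)}")
    keys = [(r.chrom, r.pos) for r in records]
    if keys != sorted(keys):
        raise ValueError("records must be sorted by (chrom, pos)")

    loci: list[QtlLocus] = []
    chunk: list[SummaryStatRecord] = []

    def flush() -> None:
        if chunk and min(s.pval for s in chunk) < config.index_p_threshold:
            loci.append(QtlLocus(
                gene_id=chunk[0].gene_id, chrom=chunk[0].chrom,
                start=chunk[0].pos, end=chunk[-1].pos, snps=list(chunk)))

    for rec in records:
        if chunk and (rec.chrom != chunk[-1].chrom
                      or rec.pos - chunk[-1].pos >= config.clump_gap):
            flush()
            chunk = []
        chunk.append(rec)
    flush()
    return loci


def classify_locus(locus: QtlLocus, gene: GeneAnnotation,
                   config: PipelineConfig) -> QtlLocus:
    """Label a locus cis or trans relative to the gene's transcription site.

    Cis iff the locus chromosome equals the gene's and the nearest SNP in the
    clump lies within ``cis_window`` of the TSS; trans otherwise.
    """
    if locus.chrom == gene.chrom:
        dist = min(abs(s.pos - gene.tss) for s in locus.snps)
        cls = "cis" if dist <= config.cis_window else "trans"
    else:
        cls = "trans"
    return replace(locus, locus_class=cls, snps=list(locus.snps))


def exclude_hla(loci: list[QtlLocus], config: PipelineConfig) -> list[QtlLocus]:
    """Drop trans loci overlapping the HLA interval; cis loci are untouched.

    The HLA region is a trans-QTL hotspot for immune genes and its disease
    associations are confounded by direct HLA effects, so it is excluded
    from genome-wide trans aggregation.
    """
    kept: list[QtlLocus] = []
    for loc in loci:
        overlaps = (loc.locus_class == "trans"
                    and loc.chrom == config.hla_chrom
                    and loc.start <= config.hla_end
                    and loc.end >= config.hla_start)
        if overlaps:
            logger.info("excluded HLA-region trans locus %s %s:%d-%d",
                        loc.gene_id, loc.chrom, loc.start, loc.end)
        else:
            kept.append(loc)
    return kept


def adjust_weights(locus: QtlLocus, panel: LdReference,
                   config: PipelineConfig) -> QtlLocus:
    """LD-adjust a locus's univariate betas into multivariable weights.

    Working on the per-SD scale: b_sd = sd * b, solve
    ``((1 - lambda) R + lambda I) w_sd = b_sd``, then w = w_sd / sd.
    With lambda = 0 and panel = QTL-study sample this equals the OLS multiple
    regression coefficient vector of expression on the locus dosages.

    SNPs absent from the panel (or strand-ambiguous / allele-inconsistent)
    are dropped with a warning; alleles swapped relative to the panel flip
    the sign of beta.
    """
    cols, signs, kept = [], [], []
    for rec in locus.snps:
        j = panel.snp_column(rec.chrom, rec.pos)
        if j is None:
            logger.warning("SNP %s:%d missing from LD panel; dropped", rec.chrom, rec.pos)
            continue
        orient = allele_orientation(rec.effect_allele, rec.other_allele,
                                    panel.snp_map["effect_allele"].iat[j],
                                    panel.snp_map["other_allele"].iat[j])
        if orient is None:
            logger.warning("SNP %s:%d strand-ambiguous or allele-inconsistent "
                           "with panel; dropped", rec.chrom, rec.pos)
            continue
        cols.append(j)
        signs.append(orient)
        kept.append(rec)
    if not kept:
        raise ValueError(f"no SNPs of locus {locus.chrom}:{locus.start}-{locus.end} "
                         "usable with the LD panel")

    cols = np.asarray(cols)
    signs = np.asarray(signs, dtype=float)
    b = np.array([r.beta for r in kept]) * signs
    R = panel.correlation(cols)
    sds = panel.dose_sds(cols)
    if np.any(~np.isfinite(R)) or np.any(sds <= 0):
        raise ValueError("LD panel has zero-variance SNPs at this locus")
    lam = config.ld_shrinkage
    R_lam = (1.0 - lam) * R + lam * np.eye(len(b))
    if np.linalg.cond(R_lam) > 1e12:
        raise np.linalg.LinAlgError(
            "shrunken LD correlation matrix is numerically singular; "
            "increase ld_shrinkage")
    w_sd = np.linalg.solve(R_lam, sds * b)
    w = w_sd / sds
    # store records in panel orientation so weights, betas and doses align
    oriented = [
        rec if s > 0 else replace(
            rec, effect_allele=rec.other_allele, other_allele=rec.effect_allele,
            beta=-rec.beta)
        for rec, s in zip(kept, signs)
    ]
    return replace(locus, snps=oriented, weights=w,
                   start=min(r.pos for r in oriented),
                   end=max(r.pos for r in oriented))


def loci_table(loci: list[QtlLocus]) -> pd.DataFrame:
    """Tabular locus summary: gene, interval, SNP count, class, min P."""
    return pd.DataFrame(
        [(l.gene_id, l.chrom, l.start, l.end, l.n_snps, l.locus_class, l.min_pval)
         for l in loci],
        columns=["gene_id", "chrom", "start", "end", "n_snps", "locus_class", "min_pval"],
    )
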