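"""Efficient-score association tests, candidate filtering and QTL sharing.

A single null logistic regression of disease on covariates is fitted per
cohort; every genotypic score (GATE trans score, cis score, single-locus
score) or measured feature is then tested with the efficient score statistic

    U = g' (y - mu),    V = g' W g - g' W C (C' W C)^{-1} C' W g,

where mu are the null fitted probabilities, W = diag(mu (1 - mu)) and C the
covariate matrix.  z = U / sqrt(V) is referred to the normal distribution;
beta = U / V is the one-step log odds ratio per unit score and
beta_std = beta * SD(score) the log odds ratio per standard deviation.

Candidate genes are those whose GATE score has an effective number of
trans-QTLs above the diversity threshold and is disease-associated at the
primary threshold (or the relaxed threshold when a known GWAS hit lies near
the gene's transcription site).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster import hierarchy
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import squareform

from .gate_scores import GateScore
from .io_formats import CohortData, GeneAnnotation, PipelineConfig
from .qtl_loci import QtlLocus

logger = logging.getLogger("gatescores")

_SEP_EPS = 1e-10  # fitted probabilities this close to 0/1 indicate separation
_V_EPS = 1e-12    # effective information below this => score is in covariate span


@dataclass
class NullModel:
    """Null logistic fit: fitted probabilities, covariates and projections."""

    sample_ids: list[str]
    y: np.ndarray
    C: np.ndarray
    mu: np.ndarray
    coef: np.ndarray
    converged: bool
    keep_mask: np.ndarray  # mask into the original cohort sample order
    _chol: tuple = field(default=None, repr=False)

    @property
    def w(self) -> np.ndarray:
        return self.mu * (1.0 - self.mu)

    def subset(self, values: np.ndarray) -> np.ndarray:
        """Restrict a full-cohort per-sample vector to the fitted samples."""
        values = np.asarray(values, dtype=float)
        if len(values) == len(self.y):
            return values
        if len(values) == len(self.keep_mask):
            return values[self.keep_mask]
        raise ValueError("score length matches neither the cohort nor the fitted samples")


@dataclass
class ScoreTestResult:
    """Efficient-score statistics for one score against disease."""

    gene_id: str
    score_type: str  # trans | cis | locus | measured
    U: float
    V: float
    z: float | None
    pval: float | None
    beta: float | None
    beta_std: float | None
    score_sd: float
    n: int
    effective_n: float | None = None
    testable: bool = True
    r2: float | None = None


def fit_null(cohort: CohortData) -> NullModel:
    """Fit the null logistic model of disease on covariates.

    Samples listed in ``cohort.exclusions`` are removed before fitting.
    Raises on a single-class phenotype, rank-deficient covariates (naming
    the collinear columns) and quasi-separation.
    """
    mask = np.array([s not in cohort.exclusions for s in cohort.sample_ids])
    y = cohort.phenotype[mask].astype(float)
    C = cohort.covariates[mask]
    ids = [s for s, m in zip(cohort.sample_ids, mask) if m]
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype has a single class; cannot fit the null model")
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        # name columns whose removal restores full rank
        bad = []
        for j in range(C.shape[1]):
            others = np.delete(C, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(cohort.covariate_names[j])
        raise ValueError(f"covariate matrix is rank deficient; collinear columns: {bad}")

    res = sm.GLM(y, C, family=sm.families.Binomial()).fit(maxiter=50, tol=1e-8)
    mu = np.asarray(res.fittedvalues)
    if np.any(mu < _SEP_EPS) or np.any(mu > 1.0 - _SEP_EPS):
        raise ValueError("quasi-separation detected: fitted probabilities at 0/1")
    null = NullModel(sample_ids=ids, y=y, C=C, mu=mu,
                     coef=np.asarray(res.params), converged=bool(res.converged),
                     keep_mask=mask)
    W = null.w
    null._chol = cho_factor((C * W[:, None]).T @ C)
    return null


def score_test(score_values: np.ndarray, null: NullModel,
               gene_id: str = "", score_type: str = "trans",
               effective_n: float | None = None) -> ScoreTestResult:
    """Efficient-score test of a per-sample score against disease.

    The score is projected off the covariates in the information metric; no
    per-score model refit is needed.  A score lying in the covariate span
    (V <= 1e-12) is flagged untestable.
    """
    g = null.subset(score_values)
    sd = float(np.std(g, ddof=1))
    if sd <= 0:
        raise ValueError(f"score for {gene_id or score_type} has zero variance")
    W = null.w
    gW = g * W
    U = float(g @ (null.y - null.mu))
    A = null.C.T @ gW
    V = float(g @ gW - A @ cho_solve(null._chol, A))
    if V <= _V_EPS:
        logger.info("score %s (%s) lies in the covariate span; untestable",
                    gene_id, score_type)
        return ScoreTestResult(gene_id=gene_id, score_type=score_type, U=U, V=V,
                               z=None, pval=None, beta=None, beta_std=None,
                               score_sd=sd, n=len(g), effective_n=effective_n,
                               testable=False)
    z = U / np.sqrt(V)
    pval = float(2.0 * stats.norm.sf(abs(z)))
    beta = U / V
    return ScoreTestResult(gene_id=gene_id, score_type=score_type, U=U, V=V,
                           z=float(z), pval=pval, beta=float(beta),
                           beta_std=float(beta * sd), score_sd=sd, n=len(g),
                           effective_n=effective_n)


# ---------------------------------------------------------------------------
# candidate filtering


def _gwas_hit_near(gene: GeneAnnotation, gwas_hits: pd.DataFrame | None,
                   window: int) -> bool:
    if gwas_hits is None or gwas_hits.empty:
        return False
    on_chrom = gwas_hits[gwas_hits["chrom"].astype(str) == gene.chrom]
    if on_chrom.empty:
        return False
    return bool((np.abs(on_chrom["pos"].to_numpy() - gene.tss) <= window).any())


def filter_candidates(results: list[ScoreTestResult],
                      genes: dict[str, GeneAnnotation],
                      gwas_hits: pd.DataFrame | None,
                      config: PipelineConfig) -> pd.DataFrame:
    """Apply the diversity and significance filters to trans-score results.

    A gene passes iff its effective number of trans-QTLs exceeds the
    threshold AND its trans-score P is below the primary threshold, or below
    the relaxed threshold with a catalogued GWAS hit within the proximity
    window of its transcription site.  Reasons: ``primary_p``, ``gwas_hit_p``,
    ``low_diversity``, ``ns``.
    """
    rows = []
    for r in sorted((r for r in results if r.score_type == "trans"),
                    key=lambda r: r.gene_id):
        gene = genes.get(r.gene_id)
        if gene is None:
            raise KeyError(f"gene {r.gene_id} missing from annotation")
        hit = _gwas_hit_near(gene, gwas_hits, config.gwas_hit_window)
        eff = r.effective_n if r.effective_n is not None else 0.0
        pval = r.pval if (r.testable and r.pval is not None) else 1.0
        if eff <= config.min_effective_trans:
            passed, reason = False, "low_diversity"
        elif pval < config.primary_assoc_p:
            passed, reason = True, "primary_p"
        elif hit and pval < config.gwas_hit_assoc_p:
            passed, reason = True, "gwas_hit_p"
        else:
            passed, reason = False, "ns"
        rows.append({
            "gene_id": r.gene_id, "symbol": gene.symbol, "chrom": gene.chrom,
            "tss": gene.tss, "gwas_hit_within_window": hit,
            "effective_n_trans": eff, "beta_std": r.beta_std, "pval": r.pval,
            "passed": passed, "reason": reason,
        })
    return pd.DataFrame(rows, columns=[
        "gene_id", "symbol", "chrom", "tss", "gwas_hit_within_window",
        "effective_n_trans", "beta_std", "pval", "passed", "reason"])


# ---------------------------------------------------------------------------
# shared trans-QTL structure


@dataclass
class BlockOrder:
    """Correlation matrix of GATE scores reordered to near block-diagonal."""

    gene_ids: list[str]          # leaf order of the dendrogram
    correlation: pd.DataFrame    # reordered |genes| x |genes| Pearson matrix
    shared_groups: list[set[str]]  # connected components at |r| > 0.8


def correlation_block_order(scores: list[GateScore],
                            share_threshold: float = 0.8) -> BlockOrder:
    """Order GATE-score correlations by average-linkage clustering on 1 - |r|.

    Groups of scores correlated above the sharing threshold (in absolute
    value) are flagged as sharing trans-QTLs.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 GATE scores to order correlations")
    for s in scores:
        if np.std(s.values) == 0:
            raise ValueError(f"GATE score for gene {s.gene_id} is constant")
    names = [s.gene_id for s in scores]
    M = np.column_stack([s.values for s in scores])
    R = np.corrcoef(M, rowvar=False)
    dist = 1.0 - np.abs(R)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = list(hierarchy.leaves_list(Z))
    ordered = pd.DataFrame(R[np.ix_(order, order)],
                           index=[names[i] for i in order],
                           columns=[names[i] for i in order])
    # connected components of the |r| > threshold graph with >= 2 members
    adj = np.abs(R) > share_threshold
    np.fill_diagonal(adj, False)
    seen, groups = set(), []
    for i in range(len(names)):
        if i in seen:
            continue
        stack, comp = [i], {i}
        while stack:
            u = stack.pop()
            for v in np.nonzero(adj[u])[0]:
                if v not in comp:
                    comp.add(int(v))
                    stack.append(int(v))
        seen |= comp
        if len(comp) > 1:
            groups.append({names[j] for j in comp})
    return BlockOrder(gene_ids=[names[i] for i in order],
                      correlation=ordered, shared_groups=groups)


def qtl_sharing_table(candidate_genes: list[str],
                      loci: list[QtlLocus],
                      annotation: dict[str, GeneAnnotation]) -> pd.DataFrame:
    """Merge overlapping trans-QTL clumps across candidate genes.

    Trans loci of candidate genes whose [start, end] intervals overlap on the
    same chromosome are merged transitively; each merged clump is reported
    with its interval, the set of target genes it regulates in trans, and the
    annotation genes whose TSS lies inside the interval.
    """
    cand = set(candidate_genes)
    use = [l for l in loci if l.gene_id in cand and l.locus_class == "trans"]
    rows = []
    by_chrom: dict[str, list[QtlLocus]] = {}
    for l in use:
        by_chrom.setdefault(l.chrom, []).append(l)
    for chrom in sorted(by_chrom, key=lambda c: (len(c), c)):
        group = sorted(by_chrom[chrom], key=lambda l: (l.start, l.end))
        current: list[QtlLocus] = []
        cur_end = None

        def flush() -> None:
            if not current:
                return
            start = min(l.start for l in current)
            end = max(l.end for l in current)
            targets = sorted({l.gene_id for l in current})
            nearby = sorted(
                g.symbol for g in annotation.values()
                if g.chrom == chrom and start <= g.tss <= end)
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "target_genes": ",".join(targets),
                         "genes_in_clump": ",".join(nearby)})

        for l in group:
            if current and l.start <= cur_end:
                current.append(l)
                cur_end = max(cur_end, l.end)
            else:
                flush()
                current = [l]
                cur_end = l.end
        flush()
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "target_genes", "genes_in_clump"])


# ---------------------------------------------------------------------------
# measured features (e.g. plasma protein levels)


def measured_feature_association(feature: np.ndarray, cohort: CohortData,
                                 gate_values: np.ndarray | None = None,
                                 gene_id: str = "",
                                 min_samples: int = 50) -> ScoreTestResult:
    """Test a measured per-sample feature against disease.

    The feature may be missing (NaN) for samples outside the measurement
    subset; the analysis is restricted to measured samples, the null model is
    refitted on that subset, and the feature is standardized to unit SD.
    When the gene's GATE score is supplied, the r^2 between score and
    measured feature on the subset is reported.
    """
    feature = np.asarray(feature, dtype=float)
    if len(feature) != cohort.n_samples:
        raise ValueError("feature length must match the cohort")
    measured = np.isfinite(feature)
    n_meas = int(measured.sum())
    if n_meas < min_samples:
        raise ValueError(f"only {n_meas} samples have the measured feature "
                         f"(minimum {min_samples})")
    sub_ids = [s for s, m in zip(cohort.sample_ids, measured) if m]
    sub = CohortData(
        sample_ids=sub_ids,
        dosages=np.empty((n_meas, 0)),
        snp_map=cohort.snp_map.iloc[:0],
        phenotype=cohort.phenotype[measured],
        covariates=cohort.covariates[measured],
        covariate_names=cohort.covariate_names,
        exclusions=set(),
    )
    null = fit_null(sub)
    f = feature[measured]
    f_std = (f - f.mean()) / f.std(ddof=1)
    res = score_test(f_std, null, gene_id=gene_id, score_type="measured")
    if gate_values is not None:
        g = np.asarray(gate_values, dtype=float)[measured]
        if np.std(g) > 0:
            res.r2 = float(np.corrcoef(g, f)[0, 1] ** 2)
    return res
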