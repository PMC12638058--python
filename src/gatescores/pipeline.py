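"""End-to-end GATE analysis: summary statistics to candidate-gene table.

Chains the pipeline stages for every gene with retained summary statistics:
clump assignment, cis/trans classification, HLA exclusion, LD adjustment of
weights against the reference panel, per-locus and aggregated scores in the
target cohort, a single null logistic fit, efficient-score tests of the
trans (GATE) and cis scores, and the diversity/significance candidate
filter.  Per-locus disease effects feeding Mendelian randomization reuse the
same efficient-score machinery on individual locus scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association, gate_scores, mendelian_randomization, qtl_loci
from .gate_scores import GateScore, LocusScore
from .io_formats import (CohortData, GeneAnnotation, PipelineConfig,
                         SummaryStatRecord)
from .mendelian_randomization import MrModelConfig, MrResult
from .qtl_loci import LdReference, QtlLocus

logger = logging.getLogger("gatescores")


@dataclass
class GeneResult:
    """Everything the pipeline computed for one gene."""

    gene_id: str
    trans_loci: list[QtlLocus]
    cis_loci: list[QtlLocus]
    gate: GateScore | None
    trans_test: association.ScoreTestResult | None
    cis_test: association.ScoreTestResult | None
    locus_scores: list[LocusScore] = field(default_factory=list)
    locus_tests: list[association.ScoreTestResult] = field(default_factory=list)


@dataclass
class GateAnalysisResult:
    """Cohort-level null model, per-gene results and the candidate table."""

    null_model: association.NullModel
    genes: dict[str, GeneResult]
    candidates: pd.DataFrame

    def gate_score(self, gene_id: str) -> GateScore:
        g = self.genes[gene_id].gate
        if g is None:
            raise KeyError(f"gene {gene_id} has no GATE score")
        return g

    def results_table(self, annotation: dict[str, GeneAnnotation],
                      gwas_hits: pd.DataFrame | None,
                      config: PipelineConfig) -> pd.DataFrame:
        """Per-gene summary mirroring the headline association table layout."""
        rows = []
        for gene_id, gr in sorted(self.genes.items()):
            gene = annotation[gene_id]
            hit = association._gwas_hit_near(gene, gwas_hits, config.gwas_hit_window)
            tt, ct = gr.trans_test, gr.cis_test
            rows.append({
                "gene_id": gene_id, "symbol": gene.symbol, "chrom": gene.chrom,
                "tss_mb": round(gene.tss / 1e6, 2),
                "gwas_hit_within_200kb": hit,
                "effective_n_trans": (gr.gate.effective_n if gr.gate else np.nan),
                "trans_logOR": (tt.beta_std if tt and tt.testable else np.nan),
                "trans_p": (tt.pval if tt and tt.testable else np.nan),
                "cis_logOR": (ct.beta_std if ct and ct.testable else np.nan),
                "cis_p": (ct.pval if ct and ct.testable else np.nan),
            })
        return pd.DataFrame(rows)


def build_gene_loci(records: list[SummaryStatRecord],
                    gene: GeneAnnotation,
                    panel: LdReference,
                    config: PipelineConfig) -> tuple[list[QtlLocus], list[QtlLocus]]:
    """Clump, classify, HLA-filter and LD-adjust one gene's loci.

    Returns (trans loci, cis loci), each with weights set.  Loci that cannot
    be adjusted (no usable panel SNPs) are dropped with a warning.
    """
    loci = qtl_loci.assign_clumps(records, config)
    loci = [qtl_loci.classify_locus(l, gene, config) for l in loci]
    loci = qtl_loci.exclude_hla(loci, config)
    trans, cis = [], []
    for locus in loci:
        try:
            locus = qtl_loci.adjust_weights(locus, panel, config)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("dropping locus %s %s:%d-%d: %s", locus.gene_id,
                           locus.chrom, locus.start, locus.end, exc)
            continue
        (trans if locus.locus_class == "trans" else cis).append(locus)
    return trans, cis


def run_gate_analysis(records: list[SummaryStatRecord],
                      annotation: dict[str, GeneAnnotation],
                      panel: LdReference,
                      cohort: CohortData,
                      gwas_hits: pd.DataFrame | None = None,
                      config: PipelineConfig | None = None,
                      locus_level_tests: bool = False) -> GateAnalysisResult:
    """Run the full GATE association analysis.

    ``records`` must already be filtered at the summary-stat P threshold
    (the reader does this).  Set ``locus_level_tests`` to also test each
    trans locus score against disease (needed for Mendelian randomization).
    """
    config = config or PipelineConfig()
    null = association.fit_null(cohort)
    by_gene: dict[str, list[SummaryStatRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)

    genes: dict[str, GeneResult] = {}
    for gene_id, recs in sorted(by_gene.items()):
        gene = annotation.get(gene_id)
        if gene is None:
            raise KeyError(f"gene {gene_id} missing from annotation")
        trans, cis = build_gene_loci(recs, gene, panel, config)

        lscores: list[LocusScore] = []
        kept_trans: list[QtlLocus] = []
        for locus in trans:
            try:
                lscores.append(gate_scores.locus_score(cohort, locus))
                kept_trans.append(locus)
            except ValueError as exc:
                logger.warning("dropping trans locus of %s: %s", gene_id, exc)
        cscores: list[LocusScore] = []
        kept_cis: list[QtlLocus] = []
        for locus in cis:
            try:
                cscores.append(gate_scores.locus_score(cohort, locus))
                kept_cis.append(locus)
            except ValueError as exc:
                logger.warning("dropping cis locus of %s: %s", gene_id, exc)

        gate = gate_scores.aggregate(gene_id, lscores, cscores)
        trans_test = cis_test = None
        ltests: list[association.ScoreTestResult] = []
        if gate is not None:
            trans_test = association.score_test(
                gate.values, null, gene_id=gene_id, score_type="trans",
                effective_n=gate.effective_n)
            if gate.cis_values is not None and np.std(gate.cis_values) > 0:
                cis_test = association.score_test(
                    gate.cis_values, null, gene_id=gene_id, score_type="cis")
            if locus_level_tests:
                ltests = [association.score_test(ls.values, null, gene_id=gene_id,
                                                 score_type="locus")
                          for ls in lscores]
        genes[gene_id] = GeneResult(
            gene_id=gene_id, trans_loci=kept_trans, cis_loci=kept_cis,
            gate=gate, trans_test=trans_test, cis_test=cis_test,
            locus_scores=lscores, locus_tests=ltests)

    trans_results = [g.trans_test for g in genes.values() if g.trans_test is not None]
    candidates = association.filter_candidates(trans_results, annotation,
                                               gwas_hits, config)
    return GateAnalysisResult(null_model=null, genes=genes, candidates=candidates)


def run_mr(result: GateAnalysisResult, gene_id: str, cohort: CohortData,
           config: PipelineConfig | None = None,
           mr_config: MrModelConfig | None = None) -> MrResult | None:
    """Dose-response MR for one gene from its per-locus tests.

    Requires ``run_gate_analysis(..., locus_level_tests=True)``.  Returns
    None when the gene has fewer than the minimum number of instruments.
    """
    config = config or PipelineConfig()
    gr = result.genes[gene_id]
    if not gr.locus_tests:
        raise ValueError("per-locus tests missing; rerun with locus_level_tests=True")
    instr = mendelian_randomization.build_instruments(
        gene_id, gr.trans_loci, gr.locus_tests, cohort, config)
    if instr is None:
        return None
    return mendelian_randomization.marginal_likelihood(instr, mr_config)
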