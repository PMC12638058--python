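"""Synthetic inputs with the statistical structure the GATE analysis assumes.

The generator emulates an omnigenic core-gene architecture: LD-blocked
diploid genotypes (Gaussian-copula thresholding of block-autocorrelated
latent variables — this preserves the only genotype properties the pipeline
consumes, allele frequency and local LD), gene expression driven by many
dispersed weak trans-effects plus an optional cis-effect, per-SNP univariate
QTL summary statistics from a simulated expression GWAS, and a case-control
cohort whose disease risk is logistic in the standardized expression of the
core gene(s) plus covariates and optional direct SNP effects.

The default architecture plants one core gene with 8 recoverable trans loci
spread over 6 chromosomes, one additional trans locus inside the configured
HLA interval (exercising the exclusion rule), and one cis locus near the
transcription site (exercising cis/trans separation), plus two decoy genes
with their own trans architecture but no effect on disease.  Its trans
heritability of expression is ~0.3 and the disease log odds ratio per SD of
core-gene expression is 0.3 at a background prevalence of 0.1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cholesky, toeplitz

from .io_formats import (CohortData, GeneAnnotation, PipelineConfig,
                         write_dosage_matrix, write_gene_annotation,
                         write_summary_stats, write_table)
from .mendelian_randomization import InstrumentSet

logger = logging.getLogger("gatescores")

_BLOCK_SPACING = 3_000_000   # bp between block anchors (> clump gap, so each
_SNP_SPACING = 5_000         # block clumps on its own); bp between SNPs


@dataclass(frozen=True)
class GeneSpec:
    """One gene of the architecture: position, cis effect, trans effects."""

    gene_id: str
    symbol: str
    chrom: str
    tss: int
    cis_effect: float = 0.0                      # applied to the SNP at the TSS block
    trans_effects: tuple = ()                    # ((global snp index, beta), ...)


@dataclass(frozen=True)
class DiseaseSpec:
    """Logistic disease model on standardized core-gene expression."""

    intercept: float = math.log(1 / 9)           # background prevalence 0.1
    gamma: tuple = ()                            # ((gene_id, log OR per SD), ...)
    covariate_effects: tuple = (0.25, 0.1, 0.1, 0.1)  # sex + 3 PC-like covariates
    direct_snp_effects: tuple = ()               # ((global snp index, log OR per dose), ...)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Full generative specification of the synthetic study."""

    n_chromosomes: int = 8
    blocks_per_chrom: int = 10
    snps_per_block: int = 8
    ld_rho: float = 0.6
    maf_range: tuple = (0.05, 0.5)
    genes: tuple = ()
    expression_noise_sd: float = 1.0
    disease: DiseaseSpec = field(default_factory=DiseaseSpec)
    n_gwas: int = 5_000
    n_cohort: int = 20_000
    n_ref: int = 2_000
    seed: int = 20_240

    def __post_init__(self) -> None:
        if not abs(self.ld_rho) < 1:
            raise ValueError("|ld_rho| must be < 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("MAF range must lie in (0, 0.5]")
        if self.genes and not any(
                self._n_trans_blocks(g) >= 6 for g in self.genes):
            raise ValueError("at least one gene needs >= 6 trans-effect loci")

    # ---- coordinate helpers -------------------------------------------------

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.blocks_per_chrom * self.snps_per_block

    @property
    def chrom_labels(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]

    def snp_index(self, chrom: str, block: int, offset: int) -> int:
        c = self.chrom_labels.index(chrom)
        return (c * self.blocks_per_chrom + block) * self.snps_per_block + offset

    def snp_position(self, block: int, offset: int) -> int:
        return (block + 1) * _BLOCK_SPACING + offset * _SNP_SPACING

    def snp_chrom_pos(self, idx: int) -> tuple[str, int]:
        per_chrom = self.blocks_per_chrom * self.snps_per_block
        c, rest = divmod(idx, per_chrom)
        block, offset = divmod(rest, self.snps_per_block)
        return self.chrom_labels[c], self.snp_position(block, offset)

    def _n_trans_blocks(self, g: GeneSpec) -> int:
        blocks = set()
        for idx, _ in g.trans_effects:
            chrom, pos = self.snp_chrom_pos(idx)
            if chrom != g.chrom or abs(pos - g.tss) > 5_000_000:
                blocks.add((chrom, pos // _BLOCK_SPACING))
        return len(blocks)

    @cached_property
    def mafs(self) -> np.ndarray:
        """Per-SNP minor allele frequencies, fixed by the architecture seed."""
        rng = np.random.default_rng(np.random.SeedSequence((self.seed, 7)))
        lo, hi = self.maf_range
        return rng.uniform(lo, hi, size=self.n_snps)

    @cached_property
    def snp_map(self) -> pd.DataFrame:
        rows = []
        for idx in range(self.n_snps):
            chrom, pos = self.snp_chrom_pos(idx)
            rows.append((chrom, pos, "A", "G"))  # non-palindromic throughout
        return pd.DataFrame(rows, columns=["chrom", "pos", "effect_allele", "other_allele"])

    def annotation(self) -> dict[str, GeneAnnotation]:
        return {g.gene_id: GeneAnnotation(g.gene_id, g.symbol, g.chrom, g.tss)
                for g in self.genes}

    def planted_trans_blocks(self, gene_id: str) -> list[tuple[str, int]]:
        """(chrom, block start bp) of each planted non-HLA trans locus."""
        g = next(gs for gs in self.genes if gs.gene_id == gene_id)
        cfg = PipelineConfig()
        blocks = set()
        for idx, _ in g.trans_effects:
            chrom, pos = self.snp_chrom_pos(idx)
            block_start = (pos // _BLOCK_SPACING) * _BLOCK_SPACING
            is_trans = chrom != g.chrom or abs(pos - g.tss) > 5_000_000
            in_hla = (chrom == cfg.hla_chrom
                      and cfg.hla_start <= pos <= cfg.hla_end)
            if is_trans and not in_hla:
                blocks.add((chrom, block_start))
        return sorted(blocks)


# ---------------------------------------------------------------------------
# default architecture


def _locus_betas(spec_mafs: np.ndarray, snp_indices: list[int],
                 target_var: float, sign: float) -> list[tuple[int, float]]:
    """Betas for one locus sized so the locus genetic variance ~ target_var.

    Within-block LD inflates the variance of the summed effect; the analytic
    sizing uses an average inflation factor of ~1.6 for 3 adjacent SNPs at
    the default latent autocorrelation.
    """
    per_snp = target_var / (len(snp_indices) * 1.6)
    out = []
    for idx in snp_indices:
        maf = spec_mafs[idx]
        var_d = 2 * maf * (1 - maf)
        out.append((idx, sign * math.sqrt(per_snp / var_d)))
    return out


def default_spec(n_gwas: int = 5_000, n_cohort: int = 20_000,
                 n_ref: int = 2_000, seed: int = 20_240,
                 gamma_core: float = 0.3) -> ArchitectureSpec:
    """The default omnigenic core-gene architecture (see module docstring)."""
    base = ArchitectureSpec(n_gwas=n_gwas, n_cohort=n_cohort, n_ref=n_ref, seed=seed)
    mafs = base.mafs

    def snps(chrom: str, block: int) -> list[int]:
        return [base.snp_index(chrom, block, o) for o in (2, 4, 6)]

    per_locus_var = 0.056  # 8 loci -> trans genetic variance ~ 0.45 (h2_trans ~ 0.3)
    core_blocks = [("2", 1), ("2", 6), ("3", 2), ("4", 3),
                   ("5", 4), ("5", 8), ("7", 5), ("8", 2)]
    trans = []
    for i, (chrom, block) in enumerate(core_blocks):
        sign = 1.0 if i % 2 == 0 else -1.0
        trans += _locus_betas(mafs, snps(chrom, block), per_locus_var, sign)
    # one trans locus inside the HLA interval (chr6 block at 27 Mb)
    trans += _locus_betas(mafs, snps("6", 8), per_locus_var, 1.0)
    core = GeneSpec("CORE1", "CORE1", chrom="1", tss=3_020_000,
                    cis_effect=math.sqrt(0.05 / 0.42), trans_effects=tuple(trans))

    decoy1_blocks = [("1", 5), ("2", 3), ("4", 6), ("5", 1),
                     ("7", 2), ("8", 5), ("8", 8), ("4", 8)]
    d1 = []
    for i, (chrom, block) in enumerate(decoy1_blocks):
        d1 += _locus_betas(mafs, snps(chrom, block), per_locus_var,
                           1.0 if i % 2 else -1.0)
    decoy1 = GeneSpec("DECOY1", "DECOY1", chrom="3", tss=9_020_000,
                      cis_effect=math.sqrt(0.05 / 0.42), trans_effects=tuple(d1))

    decoy2_blocks = [("1", 8), ("2", 8), ("3", 6), ("5", 6),
                     ("6", 1), ("7", 8), ("8", 6), ("4", 1)]
    d2 = []
    for i, (chrom, block) in enumerate(decoy2_blocks):
        d2 += _locus_betas(mafs, snps(chrom, block), per_locus_var,
                           1.0 if i % 3 else -1.0)
    decoy2 = GeneSpec("DECOY2", "DECOY2", chrom="7", tss=21_020_000,
                      trans_effects=tuple(d2))

    return replace(base, genes=(core, decoy1, decoy2),
                   disease=DiseaseSpec(gamma=(("CORE1", gamma_core),)))


# ---------------------------------------------------------------------------
# generators


def simulate_genotypes(spec: ArchitectureSpec, n: int,
                       seed: int) -> tuple[np.ndarray, pd.DataFrame]:
    """LD-blocked diploid dosages via Gaussian-copula thresholding.

    Per block, each of the two gametes is a latent multivariate normal with
    correlation rho^|i-j|; a SNP's allele indicator is the latent value
    falling below the MAF quantile, and the dose is the sum over gametes.
    """
    if n < 2:
        raise ValueError("need at least 2 individuals")
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, seed, 11)))
    m = spec.snps_per_block
    L = cholesky(toeplitz(spec.ld_rho ** np.arange(m)), lower=True)
    thresholds = stats.norm.ppf(spec.mafs)
    n_blocks = spec.n_chromosomes * spec.blocks_per_chrom
    dos = np.empty((n, spec.n_snps), dtype=float)
    for b in range(n_blocks):
        sl = slice(b * m, (b + 1) * m)
        t = thresholds[sl]
        z1 = rng.standard_normal((n, m)) @ L.T
        z2 = rng.standard_normal((n, m)) @ L.T
        dos[:, sl] = (z1 < t).astype(float) + (z2 < t)
    return dos, spec.snp_map.copy()


def true_expression(spec: ArchitectureSpec, dosages: np.ndarray,
                    rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(expression, genetic component) per gene given dosages."""
    n = dosages.shape[0]
    expr, genetic = {}, {}
    for g in spec.genes:
        comp = np.zeros(n)
        for idx, beta in g.trans_effects:
            comp += beta * dosages[:, idx]
        if g.cis_effect:
            block = g.tss // _BLOCK_SPACING - 1
            offset = round((g.tss - (block + 1) * _BLOCK_SPACING) / _SNP_SPACING)
            offset = min(max(offset, 0), spec.snps_per_block - 1)
            cis_idx = spec.snp_index(g.chrom, block, offset)
            comp = comp + g.cis_effect * dosages[:, cis_idx]
        genetic[g.gene_id] = comp
        expr[g.gene_id] = comp + rng.normal(0, spec.expression_noise_sd, size=n)
    return pd.DataFrame(expr), pd.DataFrame(genetic)


def simulate_expression_and_sumstats(spec: ArchitectureSpec, seed: int
                                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the QTL GWAS and return (expression, summary-stat table).

    For every SNP x gene pair, the univariate regression of expression on
    dose gives beta, its SE and the two-sided t-test P-value, in the
    summary-statistic column layout.
    """
    dosages, snp_map = simulate_genotypes(spec, spec.n_gwas, seed=seed * 2 + 1)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, seed, 13)))
    expr, _ = true_expression(spec, dosages, rng)

    n = spec.n_gwas
    Dc = dosages - dosages.mean(axis=0)
    Sxx = (Dc ** 2).sum(axis=0)
    frames = []
    for gene_id in expr.columns:
        y = expr[gene_id].to_numpy()
        yc = y - y.mean()
        Syy = float(yc @ yc)
        Sxy = Dc.T @ yc
        beta = Sxy / Sxx
        ssr = np.maximum(Syy - beta * Sxy, 1e-300)
        se = np.sqrt(ssr / (n - 2) / Sxx)
        tstat = beta / se
        pval = np.clip(2 * stats.t.sf(np.abs(tstat), df=n - 2), 1e-300, 1.0)
        df = snp_map.copy()
        df.insert(0, "gene_id", gene_id)
        df["beta"] = beta
        df["se"] = se
        df["pval"] = pval
        df["n"] = n
        frames.append(df)
    sumstats = pd.concat(frames, ignore_index=True)
    return expr, sumstats


def simulate_cohort(spec: ArchitectureSpec, seed: int) -> tuple[CohortData, pd.DataFrame]:
    """Simulate the target case-control cohort.

    Fresh genotypes, covariates (binary sex-like + 3 standard-normal
    components + intercept), latent expression recomputed, and a Bernoulli
    phenotype from P(case) = logistic(intercept + sum_g gamma_g *
    standardized expression_g + covariate effects + direct SNP effects).
    Returns the cohort and the per-gene true expression (for validation).
    """
    dosages, snp_map = simulate_genotypes(spec, spec.n_cohort, seed=seed * 2)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, seed, 17)))
    expr, _ = true_expression(spec, dosages, rng)
    n = spec.n_cohort

    sex = rng.integers(0, 2, size=n).astype(float)
    pcs = rng.standard_normal((n, 3))
    C = np.column_stack([np.ones(n), sex, pcs])
    cov_names = ["intercept", "sex", "pc1", "pc2", "pc3"]

    eta = np.full(n, spec.disease.intercept)
    for gene_id, gamma in spec.disease.gamma:
        e = expr[gene_id].to_numpy()
        eta += gamma * (e - e.mean()) / e.std(ddof=1)
    delta = np.asarray(spec.disease.covariate_effects, float)
    eta += C[:, 1:1 + len(delta)] @ delta
    for idx, eff in spec.disease.direct_snp_effects:
        eta += eff * dosages[:, idx]
    p = 1.0 / (1.0 + np.exp(-eta))
    expected_cases = float(p.sum())
    if expected_cases < 50:
        raise ValueError(f"expected case count {expected_cases:.1f} < 50; "
                         "increase n_cohort or the disease intercept")
    y = rng.binomial(1, p)
    cohort = CohortData(
        sample_ids=[f"S{i:06d}" for i in range(n)],
        dosages=dosages, snp_map=snp_map, phenotype=y,
        covariates=C, covariate_names=cov_names)
    return cohort, expr


def simulate_reference_panel(spec: ArchitectureSpec, seed: int
                             ) -> tuple[np.ndarray, pd.DataFrame]:
    """Independent reference-panel genotypes for LD estimation."""
    return simulate_genotypes(spec, spec.n_ref, seed=seed * 2 + 5)


def simulate_mr_instruments(K: int, theta: float, pleiotropy_frac: float,
                            alpha_sd: float, se: float, seed: int) -> InstrumentSet:
    """Test-bed instrument sets for the MR module.

    x_j ~ N(0,1); a fraction of instruments receive direct effects
    alpha_j ~ N(0, alpha_sd^2); y_j ~ N(theta x_j + alpha_j, se^2).
    """
    if K < 1:
        raise ValueError("need at least one instrument")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(K)
    alpha = np.where(rng.random(K) < pleiotropy_frac,
                     rng.normal(0, alpha_sd, size=K), 0.0)
    y = rng.normal(theta * x + alpha, se)
    return InstrumentSet(gene_id="SIM", x=x, s_x=np.zeros(K),
                         y=y, s_y=np.full(K, float(se)))


# ---------------------------------------------------------------------------
# full input bundle on disk


def default_gwas_hits(spec: ArchitectureSpec) -> pd.DataFrame:
    """A small GWAS-hit catalogue: one hit near DECOY1's TSS, one far away."""
    rows = []
    for g in spec.genes:
        if g.gene_id == "DECOY1":
            rows.append((g.chrom, g.tss + 50_000, f"HIT_NEAR_{g.symbol}"))
    rows.append(("2", 29_500_000, "HIT_UNRELATED"))
    return pd.DataFrame(rows, columns=["chrom", "pos", "label"])


def write_bundle(spec: ArchitectureSpec, outdir: str | Path, seed: int) -> dict[str, Path]:
    """Write the full pipeline input bundle to a directory.

    Produces summary statistics, reference-panel and cohort dosage matrices
    with SNP-map sidecars, phenotype, covariates, gene annotation, GWAS-hit
    catalogue and a pipeline config — all readable by ``io_formats`` without
    modification.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in {
        "summary_stats": "summary_stats.tsv",
        "panel_dosages": "panel_dosages.tsv",
        "panel_snps": "panel_dosages.tsv.snps.tsv",
        "cohort_dosages": "cohort_dosages.tsv",
        "cohort_snps": "cohort_dosages.tsv.snps.tsv",
        "phenotype": "phenotype.tsv",
        "covariates": "covariates.tsv",
        "annotation": "annotation.tsv",
        "gwas_hits": "gwas_hits.tsv",
        "config": "config.yaml",
    }.items()}

    _, sumstats = simulate_expression_and_sumstats(spec, seed=seed)
    write_summary_stats(sumstats, paths["summary_stats"])

    panel_dos, panel_map = simulate_reference_panel(spec, seed=seed)
    write_dosage_matrix([f"R{i:05d}" for i in range(spec.n_ref)],
                        panel_dos, panel_map,
                        paths["panel_dosages"], paths["panel_snps"])

    cohort, _ = simulate_cohort(spec, seed=seed)
    write_dosage_matrix(cohort.sample_ids, cohort.dosages, cohort.snp_map,
                        paths["cohort_dosages"], paths["cohort_snps"])
    write_table(pd.DataFrame({"sample_id": cohort.sample_ids,
                              "phenotype": cohort.phenotype}), paths["phenotype"])
    cov_df = pd.DataFrame(cohort.covariates, columns=cohort.covariate_names)
    cov_df.insert(0, "sample_id", cohort.sample_ids)
    write_table(cov_df, paths["covariates"])

    write_gene_annotation(spec.annotation().values(), paths["annotation"])
    write_table(default_gwas_hits(spec), paths["gwas_hits"])
    PipelineConfig(seed=seed).to_file(paths["config"])
    logger.info("wrote synthetic input bundle to %s", outdir)
    return paths
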