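"""Readers, writers, configuration and domain types for the GATE pipeline.

All external formats are plain tab-delimited text (or VCF for genotypes);
every other module consumes only the domain types defined here:

* :class:`SummaryStatRecord` — one SNP's univariate effect on one gene.
* :class:`GeneAnnotation` — gene symbol and transcription-site position.
* :class:`CohortData` — target-cohort dosages, binary phenotype, covariates.
* :class:`PipelineConfig` — every tunable threshold of the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("gatescores")

SUMMARY_STAT_COLUMNS = [
    "gene_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pval", "n",
]

ANNOTATION_COLUMNS = ["gene_id", "symbol", "chrom", "tss"]
GWAS_HIT_COLUMNS = ["chrom", "pos", "label"]

# Palindromic pairs whose strand cannot be resolved from allele labels alone.
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


def setup_logging(logfile: str | Path | None = None, level: int = logging.INFO) -> None:
    """Log to stderr and optionally to a run log file."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    logger.setLevel(level)
    for h in handlers:
        h.setFormatter(fmt)
        logger.addHandler(h)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable constants of the pipeline (positions in base pairs).

    Defaults implement the published analysis settings: SNPs filtered at
    P < 1e-5, clump index rule P < 1e-6, clumps separated by >= 1 Mb,
    cis window 5 Mb, HLA interval chr6:25-34 Mb excluded from trans scores,
    candidate filter at effective trans-QTLs > 5 with P < 1e-5 (or P < 1e-4
    with a GWAS hit within 200 kb of the TSS), and Mendelian-randomization
    analysis restricted to genes with >= 10 trans-QTLs.
    """

    snp_p_threshold: float = 1e-5
    index_p_threshold: float = 1e-6
    clump_gap: int = 1_000_000
    cis_window: int = 5_000_000
    hla_chrom: str = "6"
    hla_start: int = 25_000_000
    hla_end: int = 34_000_000
    min_effective_trans: float = 5.0
    primary_assoc_p: float = 1e-5
    gwas_hit_assoc_p: float = 1e-4
    gwas_hit_window: int = 200_000
    mr_min_instruments: int = 10
    ld_shrinkage: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_p_threshold", "index_p_threshold", "clump_gap",
                     "cis_window", "min_effective_trans", "primary_assoc_p",
                     "gwas_hit_assoc_p", "gwas_hit_window", "mr_min_instruments"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")
        if not self.hla_start < self.hla_end:
            raise ValueError("hla_start must be < hla_end")
        if not 0.0 <= self.ld_shrinkage <= 1.0:
            raise ValueError("ld_shrinkage must lie in [0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a `key: value` structured text (YAML subset) config file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)}, fh)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True, order=True)
class SummaryStatRecord:
    """One SNP's univariate effect on one gene's expression / protein level."""

    gene_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"se must be > 0 for {self.gene_id} {self.chrom}:{self.pos}")
        if not 0 < self.pval <= 1:
            raise ValueError(f"pval must lie in (0, 1] for {self.gene_id} {self.chrom}:{self.pos}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"identical alleles at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene identifier, symbol and 1-based transcription-site position."""

    gene_id: str
    symbol: str
    chrom: str
    tss: int

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError(f"tss must be >= 1 for {self.gene_id}")


@dataclass
class CohortData:
    """Target-cohort genotype dosages with phenotype and covariates.

    ``dosages`` is samples x SNPs with effect-allele doses in [0, 2]; missing
    values are NaN and are mean-imputed per SNP only at score-computation
    time.  ``covariates`` includes an intercept column.  ``exclusions`` holds
    sample ids to drop before association testing (e.g. overlap with the
    QTL study cohort).
    """

    sample_ids: list[str]
    dosages: np.ndarray
    snp_map: pd.DataFrame  # columns chrom, pos, effect_allele, other_allele
    phenotype: np.ndarray
    covariates: np.ndarray
    covariate_names: list[str]
    exclusions: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.phenotype = np.asarray(self.phenotype)
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.dosages.shape[1] != len(self.snp_map):
            raise ValueError("dosage column count does not match snp_map length")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("dosage row count does not match sample_ids")
        if not set(np.unique(self.phenotype)) <= {0, 1}:
            raise ValueError("phenotype must be binary 0/1")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise ValueError("dosages must lie in [0, 2] or be missing")
        self._snp_index = {
            (c, int(p)): j
            for j, (c, p) in enumerate(zip(self.snp_map["chrom"], self.snp_map["pos"]))
        }

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_column(self, chrom: str, pos: int) -> int | None:
        return self._snp_index.get((chrom, int(pos)))


# ---------------------------------------------------------------------------
# allele harmonization


def allele_orientation(effect: str, other: str,
                       ref_effect: str, ref_other: str) -> int | None:
    """Orientation of a record's alleles relative to a reference SNP.

    Returns +1 when (effect, other) match the reference orientation, -1 when
    they are swapped (beta and dosage must be flipped), and None when the SNP
    is strand-ambiguous (A/T or C/G) or the allele pairs are inconsistent.
    """
    ea, oa = effect.upper(), other.upper()
    rea, roa = ref_effect.upper(), ref_other.upper()
    if frozenset((ea, oa)) in _AMBIGUOUS or frozenset((rea, roa)) in _AMBIGUOUS:
        return None
    if (ea, oa) == (rea, roa):
        return 1
    if (ea, oa) == (roa, rea):
        return -1
    return None


# ---------------------------------------------------------------------------
# summary statistics


def read_summary_stats(path: str | Path, config: PipelineConfig) -> list[SummaryStatRecord]:
    """Read QTL summary statistics, dropping SNPs with pval >= the filter threshold.

    Rows with missing beta/se are rejected with the offending line number;
    duplicate (gene_id, chrom, pos, effect_allele) rows raise an error.
    Records are returned sorted by (gene_id, chrom, pos).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = set(SUMMARY_STAT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"summary-stat file missing columns: {sorted(missing_cols)}")
    for col in ("beta", "se", "pval"):
        vals = []
        for i, raw in enumerate(df[col]):
            try:
                v = float(raw)
                if not np.isfinite(v):
                    raise ValueError
            except (TypeError, ValueError):
                # +2: one for the header line, one for 0-based indexing
                raise ValueError(f"malformed {col} at line {i + 2} of {path}") from None
            vals.append(v)
        # note: plain float() round-trips %.17g exactly; pandas' fast csv
        # float path does not
        df[col] = vals
    df["pos"] = pd.to_numeric(df["pos"], errors="raise").astype(int)
    df["n"] = pd.to_numeric(df["n"], errors="raise").astype(int)
    dup = df.duplicated(subset=["gene_id", "chrom", "pos", "effect_allele"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate summary-stat record for {row.gene_id} {row.chrom}:{row.pos} "
            f"({row.effect_allele})"
        )
    records = summary_records_from_frame(df, config)
    logger.info("read %d summary-stat rows, retained %d at P < %.3g",
                len(df), len(records), config.snp_p_threshold)
    return records


def summary_records_from_frame(df: pd.DataFrame,
                               config: PipelineConfig) -> list[SummaryStatRecord]:
    """Apply the read-time P filter and sort to an in-memory summary table."""
    df = df[df["pval"] < config.snp_p_threshold]
    df = df.sort_values(["gene_id", "chrom", "pos"], kind="mergesort")
    return [
        SummaryStatRecord(
            gene_id=r.gene_id, chrom=str(r.chrom), pos=int(r.pos),
            effect_allele=r.effect_allele, other_allele=r.other_allele,
            beta=float(r.beta), se=float(r.se), pval=float(r.pval), n=int(r.n),
        )
        for r in df.itertuples(index=False)
    ]


def write_summary_stats(records: Iterable[SummaryStatRecord] | pd.DataFrame,
                        path: str | Path) -> None:
    if isinstance(records, pd.DataFrame):
        df = records[SUMMARY_STAT_COLUMNS]
    else:
        df = pd.DataFrame([vars(r) for r in records], columns=SUMMARY_STAT_COLUMNS)
    # %.17g keeps write -> read the identity on float64 beta/se/pval
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# gene annotation and GWAS-hit catalogue


def read_gene_annotation(path: str | Path) -> dict[str, GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id in annotation: {dup}")
    return {
        r.gene_id: GeneAnnotation(r.gene_id, r.symbol, str(r.chrom), int(r.tss))
        for r in df.itertuples(index=False)
    }


def write_gene_annotation(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame([vars(g) for g in genes], columns=ANNOTATION_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_gwas_hits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int, "label": str})
    missing = set(GWAS_HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"GWAS-hit catalogue missing columns: {sorted(missing)}")
    return df[GWAS_HIT_COLUMNS]


# ---------------------------------------------------------------------------
# cohort genotypes / phenotype / covariates


def _read_dosage_matrix(path: str | Path, snp_map_path: str | Path
                        ) -> tuple[list[str], np.ndarray, pd.DataFrame]:
    snp_map = pd.read_csv(snp_map_path, sep="\t",
                          dtype={"chrom": str, "pos": int,
                                 "effect_allele": str, "other_allele": str})
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    sample_ids = df["sample_id"].tolist()
    dos = df.drop(columns=["sample_id"]).to_numpy(dtype=float)
    if dos.shape[1] != len(snp_map):
        raise ValueError("dosage matrix and SNP map disagree on SNP count")
    return sample_ids, dos, snp_map


def _read_vcf_dosages(path: str | Path) -> tuple[list[str], np.ndarray, pd.DataFrame]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    cols, rows = [], []
    for v in vcf:
        ds = None
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
            d[d < 0] = np.nan
        else:  # fall back to hard genotype calls
            gt = np.asarray(v.gt_types, dtype=float)
            d = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        cols.append(d)
        rows.append((str(v.CHROM), int(v.POS), str(v.ALT[0]), str(v.REF)))
    snp_map = pd.DataFrame(rows, columns=["chrom", "pos", "effect_allele", "other_allele"])
    return sample_ids, np.column_stack(cols) if cols else np.empty((len(sample_ids), 0)), snp_map


def write_vcf_dosages(sample_ids: Sequence[str], dosages: np.ndarray,
                      snp_map: pd.DataFrame, path: str | Path) -> None:
    """Write dosages as a minimal VCF with a per-sample DS FORMAT field.

    The effect allele is written as ALT so that DS counts effect-allele doses.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        chroms = list(dict.fromkeys(snp_map["chrom"].astype(str)))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for j, r in enumerate(snp_map.itertuples(index=False)):
            vals = "\t".join(
                "." if np.isnan(d) else f"{d:g}" for d in dosages[:, j])
            fh.write(f"{r.chrom}\t{r.pos}\t{r.chrom}:{r.pos}\t{r.other_allele}\t"
                     f"{r.effect_allele}\t.\t.\t.\tDS\t{vals}\n")


def write_dosage_matrix(sample_ids: Sequence[str], dosages: np.ndarray,
                        snp_map: pd.DataFrame, path: str | Path,
                        snp_map_path: str | Path) -> None:
    cols = [f"{c}:{p}" for c, p in zip(snp_map["chrom"], snp_map["pos"])]
    df = pd.DataFrame(dosages, columns=cols)
    df.insert(0, "sample_id", list(sample_ids))
    df.to_csv(path, sep="\t", index=False)
    snp_map.to_csv(snp_map_path, sep="\t", index=False)


def read_cohort(genotype_path: str | Path,
                phenotype_path: str | Path,
                covariate_path: str | Path,
                snp_map_path: str | Path | None = None,
                exclusions: Iterable[str] = ()) -> CohortData:
    """Assemble a :class:`CohortData` from genotype, phenotype and covariate files.

    Genotypes may be a VCF (per-sample DS dosage field) or a tab-delimited
    samples x SNPs matrix with a SNP-map sidecar.  Sample order is harmonized
    across the three inputs (genotype order wins); samples absent from any
    input are dropped with a logged count.
    """
    gp = str(genotype_path)
    if gp.endswith(".vcf") or gp.endswith(".vcf.gz"):
        sample_ids, dosages, snp_map = _read_vcf_dosages(genotype_path)
    else:
        if snp_map_path is None:
            snp_map_path = gp + ".snps.tsv"
        sample_ids, dosages, snp_map = _read_dosage_matrix(genotype_path, snp_map_path)

    pheno = pd.read_csv(phenotype_path, sep="\t", dtype={"sample_id": str})
    cov = pd.read_csv(covariate_path, sep="\t", dtype={"sample_id": str})
    pheno = pheno.set_index("sample_id")
    cov = cov.set_index("sample_id")

    keep = [s for s in sample_ids if s in pheno.index and s in cov.index]
    dropped = len(sample_ids) - len(keep)
    if not keep:
        raise ValueError("no overlapping samples between genotypes, phenotype and covariates")
    if dropped:
        logger.info("dropped %d samples absent from phenotype or covariate files", dropped)
    idx = [sample_ids.index(s) for s in keep]
    dosages = dosages[idx]

    y = pheno.loc[keep, "phenotype"].to_numpy()
    try:
        y = y.astype(int)
    except (TypeError, ValueError) as exc:
        raise ValueError("phenotype must be binary 0/1") from exc
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("phenotype must be binary 0/1")

    cov_df = cov.loc[keep]
    if not any((cov_df[c] == 1).all() for c in cov_df.columns):
        cov_df.insert(0, "intercept", 1.0)
    return CohortData(
        sample_ids=keep,
        dosages=dosages,
        snp_map=snp_map,
        phenotype=y,
        covariates=cov_df.to_numpy(dtype=float),
        covariate_names=list(cov_df.columns),
        exclusions=set(exclusions),
    )


# ---------------------------------------------------------------------------
# tabular output writers (all TSV with headers)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
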