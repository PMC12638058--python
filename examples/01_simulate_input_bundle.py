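"""Write a small synthetic GATE input bundle and peek at its contents.

The bundle emulates everything the analysis consumes: QTL summary statistics
from an expression GWAS, a reference panel for LD, a case-control cohort with
covariates, gene annotation and a GWAS-hit catalogue.
"""

import tempfile

import pandas as pd

from gatescores import default_spec, read_summary_stats, PipelineConfig, write_bundle

spec = default_spec(n_gwas=1500, n_cohort=2000, n_ref=500, seed=11)
outdir = tempfile.mkdtemp(prefix="gate_bundle_")
paths = write_bundle(spec, outdir, seed=11)

print(f"bundle written to {outdir}:")
for name, path in paths.items():
    print(f"  {name:15s} {path.name}")

cfg = PipelineConfig()
records = read_summary_stats(paths["summary_stats"], cfg)
print(f"\n{len(records)} summary-stat records survive the P < {cfg.snp_p_threshold:g} filter")
print("first record:", records[0])
print("\nEach record is one SNP's univariate effect on one gene's expression;")
print("only SNPs this strongly associated ever enter a QTL locus.")
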