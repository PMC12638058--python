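"""Run the full GATE association analysis on a planted architecture.

Simulates the default omnigenic architecture (one core gene whose expression
raises disease risk, two decoy genes, an HLA-interval trans locus and a cis
locus), builds LD-adjusted locus scores, aggregates them into GATE scores,
and tests every gene's trans and cis scores against the disease.
"""

import gatescores as gs
from gatescores.synthetic_data import default_gwas_hits

cfg = gs.PipelineConfig()
spec = gs.default_spec(n_gwas=5000, n_cohort=20000, n_ref=2000, seed=1)

_, sumstats = gs.simulate_expression_and_sumstats(spec, seed=1)
records = gs.summary_records_from_frame(sumstats, cfg)
panel = gs.LdReference(*gs.simulate_reference_panel(spec, seed=1))
cohort, _ = gs.simulate_cohort(spec, seed=1)

res = gs.run_gate_analysis(records, spec.annotation(), panel, cohort,
                           default_gwas_hits(spec), cfg)

table = res.results_table(spec.annotation(), default_gwas_hits(spec), cfg)
print(table.to_string(index=False))
print()
print(res.candidates[["gene_id", "effective_n_trans", "pval", "passed", "reason"]]
      .to_string(index=False))
print()
print("CORE1 should pass with a positive trans log OR (its expression raises")
print("disease risk with log OR 0.3 per SD); the decoys should be null.")
print("effective_n_trans ~ 8 reflects the 8 planted unlinked trans loci —")
print("the HLA-interval locus is excluded and the cis locus tested separately.")
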