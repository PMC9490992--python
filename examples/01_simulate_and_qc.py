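"""Simulate a study population and run genotype + expression QC.

Builds a miniature of the target study design — a genotyped population of
which only a subset is transcribed — then applies the marker filters
(call rate < 90%, MAF < 0.05, HWE P < 1e-6, sample missingness > 10%)
and the expression filter (FPKM < 0.1 in more than 95% of samples).
"""

import omixblup as ob

bundle, truth = ob.make_study_bundle(n_total=300, n_transcribed=60,
                                     m=2000, g=500, seed=1)
print(f"population: {bundle.n_samples} genotyped, "
      f"{len(bundle.transcribed_idx)} transcribed")

geno_f, snp_report = ob.filter_snps(bundle.geno)
print("SNP QC removals by rule:", snp_report.n_removed_by_rule)

expr_f, gene_report = ob.filter_genes(bundle.expr)
print("gene QC removals:", gene_report.n_removed_by_rule)

# The simulator draws markers in Hardy-Weinberg equilibrium with MAF >= 0.05
# and expressed genes, so a clean panel passes almost untouched; planted
# violations (see the tests) are removed rule by rule.
print(f"{geno_f.n_markers}/{bundle.geno.n_markers} markers and "
      f"{expr_f.n_genes}/{bundle.expr.n_genes} genes survive")
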