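"""How the genotyped-only population size affects wmssBLUP vs GBLUP.

Keeps the transcribed core fixed and grows the genotyped-only population
around it, scoring both models by replicated fivefold CV on each combined
set. Each row pairs the two accuracies and their improvement; the
transcribed fraction shrinks down the table.
"""

import omixblup as ob

bundle, _ = ob.make_study_bundle(n_total=300, n_transcribed=60, m=600,
                                 g=150, h2=0.2, mediation_share=0.8,
                                 expr_h2=0.8, seed=4)
adj = ob.adjust_phenotypes(bundle.pheno)
y = adj.values_for(bundle.sample_ids)

rows = ob.proportion_experiment(bundle, y, w=0.5, k=5, replicates=5,
                                seed=10, expr_log1p=True)
print("size  n_total  frac_T  acc_wmss  acc_gblup  improvement%")
for r in rows:
    print(f"{r['size']:4d}  {r['n_total']:7d}  {r['transcribed_fraction']:.2f}"
          f"    {r['accuracy_wmss']:+.3f}    {r['accuracy_gblup']:+.3f}"
          f"     {r['improvement_pct']:+.1f}")
print("accuracies are means over 25 fold-level Pearson correlations; "
      "folds are shared between the two models within each row")
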