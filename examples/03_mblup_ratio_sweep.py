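"""Blend genomic and transcriptomic kernels: the MBLUP ratio sweep.

For a fully transcribed population, M = ratio * G + (1 - ratio) * T
interpolates between TBLUP (ratio 0) and cosine-kernel GBLUP (ratio 1).
On a trait whose genetic signal acts mostly through expression, the
leave-one-out accuracy curve peaks at a low ratio — the transcriptome
carries most of the predictive information.
"""

import numpy as np

import omixblup as ob

bundle, _ = ob.make_study_bundle(n_total=120, n_transcribed=120, m=400,
                                 g=120, h2=0.6, mediation_share=0.9,
                                 expr_h2=0.9, seed=7)
adj = ob.adjust_phenotypes(bundle.pheno)
y = adj.values_for(bundle.sample_ids)

G = ob.cosine_g(bundle.geno)
T = ob.cosine_t(bundle.expr, log1p=True)
res = ob.grid_search_ratio(G, T, y, grid=np.round(np.arange(0, 1.01, 0.1), 1))

for ratio, acc in zip(res.grid, res.accuracies):
    bar = "#" * max(0, int(40 * acc))
    print(f"ratio {ratio:3.1f}  acc {acc:+.3f}  {bar}")
print(f"best ratio = {res.best_value} (accuracy {res.best_accuracy:.3f}); "
      "ratio 0 is TBLUP, ratio 1 is GBLUP")
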