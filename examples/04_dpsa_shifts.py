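"""Differential pseudospatial analysis: detect profile shifts under fasting.

Per-gene fitted curves in each condition are compared with the fed curve by
correlation; a changed profile whose center of mass moved toward larger s is
a dorso->ventral shift, toward smaller s a ventro->dorsal shift.
"""

import tanypsa as tp
from tanypsa.pipeline import default_anchor_genes

adata, truth = tp.generate_dataset(tp.default_config(seed=1))
norm = tp.normalize(adata)
ps = tp.order_cells(norm, default_anchor_genes(norm))
by_cond = {c: tp.fit_profiles(norm[norm.obs["condition"] == c], ps)
           for c in norm.obs["condition"].cat.categories}

calls = tp.compare_conditions(by_cond)
calls24 = calls[calls["condition"] == "fasting24h"].set_index("gene")

dv = truth.gene_program.query("program == 'shifted' and shift_fasting24h > 0").index
vd = truth.gene_program.query("program == 'shifted' and shift_fasting24h < 0").index
print("planted +0.2 shift called dorso->ventral: "
      f"{(calls24.reindex(dv)['direction'] == 'dorso->ventral').mean():.0%}")
print("planted -0.2 shift called ventro->dorsal: "
      f"{(calls24.reindex(vd)['direction'] == 'ventro->dorsal').mean():.0%}")
mean_dc = calls24.reindex(dv)["delta_com"].mean()
print(f"mean center-of-mass displacement of the +0.2 genes: {mean_dc:+.3f} "
      "(the planted translation, recovered from the fitted curves)")
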