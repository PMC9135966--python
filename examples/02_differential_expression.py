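"""Cell-type-scoped differential expression on planted effects.

Simulates a cohort where NK cells overexpress two genes and the CD16
protein in the disease group, normalizes (VST for RNA, scaled CLR for
ADT), runs the NB gene test and the Wilcoxon protein test, and shows that
the planted features top the significant lists.
"""

import pandas as pd
import citeflow as cf
from citeflow.diffexpr import de_genes, de_proteins, flag_batch_artifacts
from citeflow.normalize import vst_residuals

effects = (cf.PlantedEffect("NK", "GENE0010", "RNA", 1.5),
           cf.PlantedEffect("NK", "GENE0020", "RNA", -1.2),
           cf.PlantedEffect("NK", "CD16", "ADT", 1.5))
cfg = cf.SimConfig(n_healthy=5, n_as=5, cells_per_subject=200,
                   cell_types=(cf.CellTypeSpec("NK", 1.0, 0.0),),
                   de_spec=effects, seed=1)
ds = cf.generate_cohort(cfg)
rna, adt, _ = cf.apply_qc(ds.rna, ds.adt, cf.QcThresholds())

m = vst_residuals(rna)
corrected = pd.DataFrame(m.params["corrected_counts"], index=m.cells,
                         columns=m.features)
groups = rna.obs["cohort"].astype(str)
res_g = de_genes(corrected, groups, cell_type="NK")
res_g = flag_batch_artifacts(res_g, corrected, groups,
                             rna.obs["batch"].astype(str))
print("top genes (effect = log2 FC, Bonferroni-adjusted p):")
print(res_g.head(4)[["feature", "effect", "p_adj", "significant",
                     "artifact_reason"]].to_string(index=False))
art = set(ds.truth.batch_artifact_genes.values())
flagged = set(res_g.loc[res_g["artifact_flag"], "feature"])
print(f"planted batch-artifact genes flagged: {sorted(flagged & art)}")

clr = cf.center_scale(cf.clr_normalize(adt[rna.obs_names]))
res_p = de_proteins(clr, groups, cell_type="NK")
print("\ntop proteins (effect = mean scaled difference):")
print(res_p.head(3)[["feature", "effect", "p_adj", "significant"]]
      .to_string(index=False))
# The planted GENE0010/GENE0020 and CD16 should lead both tables with
# effects near the planted log2 sizes (gene effects shrink slightly from
# the +1 pseudo-mean).
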