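"""Generate every pipeline input with planted ground truth.

Builds a low-rank region x gene expression matrix whose first 50 genes load
on a smooth spatial factor, a control/patient thickness cohort whose genetic
group atrophies along that same factor, receptor maps with prescribed
correlations to it, and a pathology gene list overlapping the planted genes.
"""

import numpy as np

from plscortex import (
    make_cohort,
    make_expression,
    make_pathology_sets,
    make_receptor_atlas,
)

expr, truth = make_expression(n_regions=50, n_genes=500, n_planted=50, seed=7)
print(f"expression matrix: {expr.shape[0]} regions x {expr.shape[1]} genes")
print(f"planted genes: {len(truth.planted_gene_ids)} "
      f"(e.g. {truth.planted_gene_ids[:3]})")

atrophy = truth.spatial_factors["factor_1"]
cohort = make_cohort(n_controls=60, n_sporadic=40, n_genetic=30,
                     atrophy_map=atrophy, effect=1.5, seed=11)
print(f"cohort: {len(cohort)} subjects, groups "
      f"{cohort['group'].value_counts().to_dict()}")

atlas, _ = make_receptor_atlas(atrophy, [0.8, -0.5, 0.0], seed=3)
for name, target in zip(atlas.receptors, [0.8, -0.5, 0.0]):
    r = np.corrcoef(atlas.densities[name], atrophy)[0, 1]
    print(f"receptor {name}: target r = {target:+.1f}, realized r = {r:+.2f}")

pathology = make_pathology_sets(list(expr.columns), truth.planted_gene_ids,
                                overlap_fraction=0.5, set_size=100, seed=5)
overlap = len(pathology & set(truth.planted_gene_ids))
print(f"pathology list: {len(pathology)} genes, {overlap} planted "
      "(half the planted set, by construction)")
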