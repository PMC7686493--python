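"""SOM biomarker maps: disease x age-stratum effect-size vectors on a
10x10 hexagonal grid, followed by hierarchical clustering of the
conditions."""

import numpy as np
import pandas as pd

import bloodmir as bm

expr, meta, _ = bm.simulate_cohort(n_samples=1000, n_mirnas=1000, seed=5)
vectors = bm.biomarker_vectors(expr, meta)  # 801 top miRNAs x 12 conditions
print(f"biomarker matrix: {vectors.shape[0]} miRNAs x "
      f"{vectors.shape[1]} conditions")

model = bm.train_som(vectors, bm.SomParams(seed=5))
occ = model.occupancy()
print(f"grid occupancy: {int((occ > 0).sum())}/100 cells, "
      f"mean {occ.mean():.2f} members/cell (sd {occ.std(ddof=1):.1f})")

heat = bm.cell_heatmap(model, vectors["HD_young"])
print(f"HD-young heat map: {int(np.nansum(np.abs(heat) > 0.5))} cells with "
      f"|mean effect| > 0.5")

cell_vectors = pd.DataFrame(
    {c: np.nan_to_num(bm.cell_heatmap(model, vectors[c]))
     for c in vectors.columns})
linkage = bm.cluster_biomarker_sets(cell_vectors)
from bloodmir.som import linkage_to_newick
print("condition dendrogram (complete linkage, Euclidean):")
print(linkage_to_newick(linkage, list(cell_vectors.columns)))
print("-> conditions merging early have similar biomarker maps")
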