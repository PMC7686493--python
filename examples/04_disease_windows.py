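"""Sliding-window disease effect sizes and deregulation counts.

Each disease group is compared against healthy controls in 10-year age
windows (starts 30..70, step 1, at least 20 cases and controls); counting
miRNAs with |Cohen's d| > 0.5 per window traces how the disease signal
changes across the lifespan."""

import numpy as np

import bloodmir as bm
from bloodmir.stats import spearman_with_p

expr, meta, truth = bm.simulate_cohort(n_samples=4000, n_mirnas=400, seed=4)

tracks = {}
for disease in ("HD", "NTLD", "LC", "PD"):
    track = bm.sliding_effect_sizes(expr, meta, disease)
    counts, _ = bm.count_deregulated(track, d_threshold=0.5)
    rho, _ = spearman_with_p(np.array(counts.index, float),
                             counts.to_numpy(float))
    tracks[disease] = track
    print(f"{disease}: deregulated miRNAs per window "
          f"{counts.iloc[0]} (age 30-39) -> {counts.iloc[-1]} (70-79), "
          f"trend SC={rho:+.2f}")
print("-> heart/lung disease signals fade with age (planted decay); the "
      "U-shaped PD profile does not trend monotonically")

global_d = {d: bm.global_effect_sizes(expr, meta, d)
            for d in ("HD", "NTLD", "LC", "PD")}
pan = bm.pan_disease_summary(global_d)
top = pan.sort_values("mean_abs_d", ascending=False).head(3)
print("\ntop pan-disease markers (n diseases relevant, mean |d|):")
print(top.round(2).to_string())
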