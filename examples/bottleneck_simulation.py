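"""Replicate variability from inoculum subsampling alone.

Builds a 314-taxon long-tailed pool with five rare fast-growing focal taxa,
runs five independent inoculate-grow-subsample replicates of 200,000 cells
each, and prints the focal taxa's starting draws and final read counts.
"""

import numpy as np

import soilcosm as sc
from soilcosm.growth import run_replicate_ensemble
from soilcosm.synth import make_focal_pool

pool = make_focal_pool(n_taxa=314, n_cells=200_000, seed=20)
params = sc.GrowthParams()  # 200 fg C/cell, 20% yield, 0.2 mg C per batch
res = run_replicate_ensemble(pool, params, n_replicates=5,
                             seeds=[101, 102, 103, 104, 105])

focal = np.flatnonzero(pool.focal_flags)
print(f"final community size per replicate: "
      f"{[f'{s:.3g}' for s in res.final_sizes]} cells")
print("focal taxon  rate(1/h)  final reads per replicate (of 200,000)")
for i in focal:
    row = res.counts.iloc[:, i].tolist()
    print(f"  {pool.taxon_ids[i]:>8} {pool.growth_rate[i]:>8.2f}  {row}")
print("\nEach replicate drew its own 200,000-cell inoculum: a focal taxon that")
print("happened to draw 0 cells stays absent, while the same taxon drawn a")
print("handful of times can grow to percent-level abundance — identical")
print("communities and conditions, divergent outcomes.")
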