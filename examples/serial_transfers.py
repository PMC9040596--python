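"""Eight weekly 1:10 growth/dilution cycles of a two-taxon community.

Shows selection under serial transfer: the faster grower is progressively
enriched, while binomial transfer sampling adds replicate noise.
"""

import numpy as np

import soilcosm as sc
from soilcosm.transfers import RegimeConfig, run_cycles

pool = sc.TaxonPool(("fast", "slow"), np.array([0.5, 0.5]), np.array([0.5, 0.2]))
params = sc.GrowthParams(S0=1e-7)  # 0.1 ug C per batch -> ~1e5 new cells/cycle
regime = RegimeConfig(n_cycles=8, dilution_factor=10, fresh_S0=params.S0,
                      sampling_depth=10_000, seeds=tuple(range(8)))

inoc = sc.sample_inoculum(pool, 10_000, seed=0)
traj = run_cycles(inoc, pool, params, regime)

print("cycle  total cells  share(fast)")
for cycle, row in traj.tables.iterrows():
    total = traj.total_sizes[cycle - 1]
    print(f"  {cycle}    {total:>10.3g}   {row['fast'] / row.sum():.3f}")
print("\nThe faster grower (0.5 vs 0.2 1/h) gains share every cycle; the total")
print("community size is set by the carbon budget, not by the growth rates.")
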