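"""Strain quantification round trip: reads -> counts -> cell abundances.

Generates a 21-strain identifier catalog with operon copy numbers 1..7,
simulates error-free amplicon reads at copy-weighted proportions, counts
identifiers, applies the operon-copy correction and anchors the result to a
flow-cytometry community size.
"""

import numpy as np

from soilcosm.amplicon import absolute_abundance, correct_and_normalize, count_identifiers
from soilcosm.synth import make_catalog, make_reads

catalog = make_catalog(n_strains=21, copy_range=(1, 7), seed=30)
rng = np.random.default_rng(31)
cell_rel = rng.dirichlet(np.ones(21) * 4)  # true cell-level composition
copies = np.array(catalog.operon_copies, dtype=float)
read_props = cell_rel * copies / (cell_rel * copies).sum()  # what sequencing sees

reads = make_reads(catalog, dict(zip(catalog.strain_ids, read_props)),
                   n_reads=20_000, seed=32)
raw, n_ambiguous = count_identifiers(reads.reads, catalog)
table = absolute_abundance(correct_and_normalize(raw, catalog), 1.11e9)

print(f"classified {table.n_classified} reads, {n_ambiguous} ambiguous")
print(table.table.head(6).to_string(float_format=lambda v: f"{v:.4g}"))
err = np.abs(table.table["rel_abundance"].to_numpy() - cell_rel).max()
print(f"\nmax |recovered - true| relative abundance: {err:.4f}")
print("Raw read counts over-represent high-copy strains; dividing by operon")
print("copies recovers the cell-level composition, here to sub-percent error,")
print("and the 1.11e9 cells/mL anchor converts shares to absolute densities.")
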