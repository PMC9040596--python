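"""Community summary metrics and printed-arithmetic calculators.

Diversity side: depth normalisation of abundance matrices (continuous rescale
to a common read total, default 5x10^4), richness at a detection threshold,
Shannon entropy (natural log), Bray-Curtis dissimilarity and per-replicate
distance to the group centroid (a beta-dispersion analogue used as the
replicate-variability measure).

Budget side: pure deterministic calculators for the numbers a microcosm study
prints — how many cells a soil's organic carbon can support, fold-increase
and doublings between two densities, the nominal molar concentration of a
solvent spike, and RockEval hydrogen/oxygen indices.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_depth",
    "richness",
    "shannon",
    "bray_curtis",
    "centroid_distances",
    "distance_matrix",
    "carbon_budget",
    "order_of_magnitude",
    "fold_and_doublings",
    "inoculation_density",
    "nominal_concentration",
    "rockeval_indices",
    "TOLUENE_DENSITY_G_PER_ML",
    "TOLUENE_MW_G_PER_MOL",
]

# physical constants for the solvent-spike calculator; overridable per call
TOLUENE_DENSITY_G_PER_ML = 0.867
TOLUENE_MW_G_PER_MOL = 92.14


def normalize_depth(m: pd.DataFrame, depth: float = 50_000) -> pd.DataFrame:
    """Rescale every sample row to a common total (continuous, no rounding)."""
    totals = m.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return m.div(totals, axis=0) * depth


def richness(row: Sequence[float] | pd.Series, detect_min: float = 1.0) -> int:
    """Number of taxa at or above the detection threshold (on normalised counts)."""
    arr = np.asarray(row, dtype=float)
    return int((arr >= detect_min).sum())


def shannon(p: Sequence[float] | pd.Series) -> float:
    """Shannon entropy H = -sum p_i ln p_i in nats; zero entries are skipped."""
    arr = np.asarray(p, dtype=float)
    arr = arr[arr > 0]
    return float(-(arr * np.log(arr)).sum())


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundance vectors must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_braycurtis(x, y))


def centroid_distances(m: pd.DataFrame, group_labels: Sequence) -> pd.Series:
    """Bray-Curtis distance of each replicate to its group's mean composition.

    The centroid is the arithmetic mean vector of the group's rows. Singleton
    groups get distance 0 with a warning.
    """
    labels = pd.Series(list(group_labels), index=m.index, name="group")
    out = pd.Series(0.0, index=m.index, name="centroid_distance")
    for g, idx in labels.groupby(labels).groups.items():
        if len(idx) < 2:
            logger.warning("group %r has a single sample; centroid distance set to 0", g)
            continue
        centroid = m.loc[idx].mean(axis=0).to_numpy()
        for i in idx:
            out[i] = bray_curtis(m.loc[i].to_numpy(), centroid)
    return out


def distance_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Square Bray-Curtis distance matrix between all sample rows."""
    n = len(m)
    arr = m.to_numpy(dtype=float)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(arr[i], arr[j])
    return pd.DataFrame(d, index=m.index, columns=m.index)


def carbon_budget(toc_g_per_g: float, Y: float = 0.2, c_cell: float = 2e-13) -> float:
    """Supportable community size from organic carbon: cells = TOC * Y / c_cell.

    With 1.5 mg TOC per g soil, a 20% carbon yield and 200 fg C per cell this
    gives ~1.5x10^9 cells per g.
    """
    if toc_g_per_g <= 0 or Y <= 0 or c_cell <= 0:
        raise ValueError("all carbon-budget inputs must be positive")
    return toc_g_per_g * Y / c_cell


def order_of_magnitude(x: float) -> int:
    """floor(log10 x) — the order of magnitude of a positive quantity."""
    if x <= 0:
        raise ValueError("order of magnitude requires a positive value")
    return math.floor(math.log10(x))


def fold_and_doublings(n0: float, nt: float) -> tuple[float, float]:
    """Fold increase nt/n0 and the equivalent number of doublings log2(nt/n0)."""
    if n0 <= 0 or nt <= 0:
        raise ValueError("densities must be positive")
    fold = nt / n0
    return fold, math.log2(fold)


def inoculation_density(volume_ml: float, cells_per_ml: float, mass_g: float) -> float:
    """Cells per g of matrix after inoculating a suspension into a microcosm.

    E.g. 10 mL at 10^7 cells/mL into 100 g soil gives 10^6 cells per g.
    """
    if volume_ml < 0 or cells_per_ml < 0 or mass_g <= 0:
        raise ValueError("volumes/densities must be non-negative; mass positive")
    return volume_ml * cells_per_ml / mass_g


def nominal_concentration(
    volume_ul: float,
    system_volume_l: float,
    density_g_per_ml: float = TOLUENE_DENSITY_G_PER_ML,
    mw_g_per_mol: float = TOLUENE_MW_G_PER_MOL,
) -> float:
    """Nominal concentration (mM) of a neat-solvent spike in a closed system.

    mM = (volume_ul * 1e-3 mL * density / MW) mol / system_volume_l * 1e3
    """
    if min(volume_ul, system_volume_l, density_g_per_ml, mw_g_per_mol) < 0 or \
            system_volume_l <= 0 or density_g_per_ml <= 0 or mw_g_per_mol <= 0:
        raise ValueError("inputs must be positive (spike volume may be zero)")
    mol = volume_ul * 1e-3 * density_g_per_ml / mw_g_per_mol
    return mol / system_volume_l * 1e3


def rockeval_indices(S2: float, S3: float, TOC: float) -> tuple[float, float]:
    """RockEval hydrogen and oxygen indices: HI = S2/TOC*100, OI = S3/TOC*100."""
    if TOC <= 0:
        raise ValueError("TOC must be positive")
    return S2 / TOC * 100.0, S3 / TOC * 100.0
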