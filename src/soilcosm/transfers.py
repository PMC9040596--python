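"""Serial growth/dilution cycles: the weekly 1:10 transfer regime.

Each cycle is one week of batch growth on fresh substrate followed by a
ten-fold dilution into a fresh sterile microcosm. Dilution is modelled as
binomial thinning of each taxon's integer cell count — a genuine stochastic
bottleneck, not a deterministic division — because transfer sampling noise is
part of what the experiment interrogates. Unconsumed substrate carbon is
carried over and added to the fresh pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import (
    CommunityState,
    GrowthParams,
    Inoculum,
    TaxonPool,
    simulate_batch,
    subsample_counts,
)

__all__ = ["RegimeConfig", "CycleTrajectory", "dilute", "run_cycles", "trajectory_long_table"]


@dataclass(frozen=True)
class RegimeConfig:
    """Serial-transfer regime: cycle count, dilution factor, fresh carbon.

    Defaults mirror the weekly 1:10 (wt/wt) transfer design repeated eight
    times, with read-depth subsampling of every cycle endpoint.
    """

    n_cycles: int = 8
    dilution_factor: float = 10.0
    fresh_S0: float = 2e-4
    sampling_depth: int = 200_000
    seeds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be at least 1")


def dilute(state: CommunityState, factor: float = 10.0, seed: int | None = None) -> Inoculum:
    """Transfer a 1/factor aliquot: binomial thinning of each taxon.

    Each cell is carried over independently with probability 1/factor, so the
    expected new total is old total / factor and rare taxa can be lost.
    Continuous counts are rounded to the nearest cell before thinning; thinning
    a community smaller than the factor usually extinguishes it.
    """
    if factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    n = np.round(state.counts).astype(np.int64)
    rng = np.random.default_rng(seed)
    return Inoculum(counts=rng.binomial(n, 1.0 / factor))


@dataclass(frozen=True)
class CycleTrajectory:
    """Per-cycle subsampled composition tables plus total-size series."""

    tables: pd.DataFrame  # rows: cycles completed; columns: taxa; subsampled counts
    total_sizes: tuple[float, ...]  # community size at the end of each cycle
    extinct: bool  # True if the community died out before finishing
    cycles_run: int


def run_cycles(
    inoc: Inoculum,
    pool: TaxonPool,
    params: GrowthParams,
    regime: RegimeConfig,
) -> CycleTrajectory:
    """Propagate a community through the serial-transfer regime.

    Per cycle: batch growth on ``fresh_S0`` (plus any carried-over substrate)
    → record a depth-subsampled composition table → binomial 1:factor dilution
    into the next cycle. If a dilution extinguishes the community the
    trajectory is truncated and flagged.
    """
    seeds = regime.seeds or tuple(range(regime.n_cycles))
    if len(seeds) < regime.n_cycles:
        raise ValueError("need at least one seed per cycle")
    rows: list[np.ndarray] = []
    totals: list[float] = []
    current = inoc
    carry_over = 0.0
    extinct = False
    for c in range(regime.n_cycles):
        if current.total == 0:
            extinct = True
            break
        ss = np.random.SeedSequence(seeds[c])
        seed_sub, seed_dil = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
        cycle_params = GrowthParams(
            K_s=params.K_s, Y=params.Y, c_cell=params.c_cell,
            S0=regime.fresh_S0 + carry_over,
        )
        state = simulate_batch(current, pool, cycle_params)
        carry_over = state.substrate
        depth = min(regime.sampling_depth, int(state.total))
        rows.append(subsample_counts(state, depth=depth, seed=seed_sub).counts)
        totals.append(state.total)
        if state.total < regime.dilution_factor:
            # too few cells to draw a 1/factor aliquot: effectively extinct
            extinct = True
            break
        current = dilute(state, regime.dilution_factor, seed=seed_dil)
    tables = pd.DataFrame(rows, columns=list(pool.taxon_ids))
    tables.index = pd.RangeIndex(1, len(rows) + 1, name="cycle")
    return CycleTrajectory(
        tables=tables,
        total_sizes=tuple(totals),
        extinct=extinct,
        cycles_run=len(rows),
    )


def trajectory_long_table(traj: CycleTrajectory, replicate: int = 0) -> pd.DataFrame:
    """Flatten a trajectory to long format (cycle, replicate, taxon_id, count, rel_abundance)."""
    recs = []
    for cycle, row in traj.tables.iterrows():
        tot = row.sum()
        for tid, count in row.items():
            recs.append(
                {
                    "cycle": cycle,
                    "replicate": replicate,
                    "taxon_id": tid,
                    "count": int(count),
                    "rel_abundance": count / tot if tot else 0.0,
                }
            )
    return pd.DataFrame(recs)
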