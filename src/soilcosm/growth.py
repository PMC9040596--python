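"""Stochastic-inoculum, carbon-limited multi-taxon Monod growth.

The generative model has three stages. A species pool with a long-tailed
rank-abundance distribution is subsampled to a finite inoculum (multinomial
draw of individual cells), the inoculum grows deterministically on a single
shared carbon pool under Monod kinetics until the carbon is depleted, and the
grown community is subsampled again to a fixed read depth (as if sequenced).
All stochasticity therefore enters through the two sampling bottlenecks; the
growth itself is an ODE:

    dN_i/dt = mu_i * S/(K_s + S) * N_i
    dS/dt   = -(c_cell / Y) * sum_i dN_i/dt

with no death, lag, or interaction terms. Because every taxon experiences the
same substrate factor, the final community size is stoichiometric
(N_tot_final = N_tot_0 + Y*S0/c_cell) while the final *composition* depends on
the growth-rate spectrum and the inoculum draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "TaxonPool",
    "GrowthParams",
    "Inoculum",
    "CommunityState",
    "EnsembleResult",
    "assign_growth_rates",
    "set_focal_rates",
    "sample_inoculum",
    "simulate_batch",
    "subsample_counts",
    "run_replicate_ensemble",
]


@dataclass(frozen=True)
class TaxonPool:
    """Species pool: ids, relative abundances, per-taxon maximum growth rates.

    Parameters
    ----------
    taxon_ids
        Unique, ordered taxon identifiers.
    rel_abundance
        Relative abundance per taxon; non-negative, sums to 1.
    growth_rate
        Maximum specific growth rate mu_max per taxon, in 1/h.
    focal_flags
        Marks taxa whose growth rates were overridden (rare fast-growers).
    """

    taxon_ids: tuple[str, ...]
    rel_abundance: np.ndarray
    growth_rate: np.ndarray
    focal_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ids = tuple(str(t) for t in self.taxon_ids)
        object.__setattr__(self, "taxon_ids", ids)
        ra = np.asarray(self.rel_abundance, dtype=float)
        gr = np.asarray(self.growth_rate, dtype=float)
        if self.focal_flags is None:
            ff = np.zeros(len(ids), dtype=bool)
        else:
            ff = np.asarray(self.focal_flags, dtype=bool)
        object.__setattr__(self, "rel_abundance", ra)
        object.__setattr__(self, "growth_rate", gr)
        object.__setattr__(self, "focal_flags", ff)
        if len(set(ids)) != len(ids):
            raise ValueError("taxon_ids must be unique")
        if not (len(ids) == ra.size == gr.size == ff.size):
            raise ValueError("pool fields must have equal length")
        if np.any(ra < 0):
            raise ValueError("relative abundances must be non-negative")
        if abs(ra.sum() - 1.0) > 1e-9:
            raise ValueError(f"relative abundances must sum to 1 (got {ra.sum()!r})")
        if np.any(~np.isfinite(gr)) or np.any(gr <= 0):
            raise ValueError("growth rates must be positive and finite")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def index_of(self, taxon_id: str) -> int:
        try:
            return self.taxon_ids.index(taxon_id)
        except ValueError:
            raise KeyError(f"unknown taxon id: {taxon_id!r}") from None


@dataclass(frozen=True)
class GrowthParams:
    """Monod kinetics and carbon stoichiometry.

    K_s : half-saturation substrate level, g C per batch volume; defaults to
        0.05*S0 (kinetic shape only — the final community size is set by
        stoichiometry, not by K_s).
    Y : yield, g biomass-C produced per g substrate-C consumed (0 < Y <= 1).
    c_cell : carbon content of one cell, g C (default 200 fg).
    S0 : initial substrate carbon per batch, g C.
    """

    K_s: float | None = None
    Y: float = 0.2
    c_cell: float = 2e-13
    S0: float = 2e-4

    def __post_init__(self) -> None:
        if self.K_s is None:
            object.__setattr__(self, "K_s", 0.05 * self.S0 if self.S0 > 0 else 1e-6)
        if not (0 < self.Y <= 1):
            raise ValueError("yield Y must lie in (0, 1]")
        if self.c_cell <= 0:
            raise ValueError("c_cell must be positive")
        if self.K_s <= 0:
            raise ValueError("K_s must be positive")
        if self.S0 < 0:
            raise ValueError("S0 must be non-negative")


@dataclass(frozen=True)
class Inoculum:
    """Integer cell counts per taxon, aligned to a TaxonPool's order."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if np.any(c < 0):
            raise ValueError("inoculum counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class CommunityState:
    """Continuous per-taxon cell counts plus remaining substrate carbon."""

    counts: np.ndarray
    substrate: float
    time: float

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", c)
        if np.any(c < 0) or self.substrate < -0.0:
            raise ValueError("state must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def assign_growth_rates(pool: TaxonPool, mu_min: float = 0.01, mu_max: float = 0.4) -> TaxonPool:
    """Map growth rates linearly in log10 relative abundance.

    The most abundant taxon gets ``mu_max`` and the rarest gets ``mu_min``:

        mu_i = mu_min + (mu_max - mu_min)
               * (log10 a_i - log10 a_min) / (log10 a_max - log10 a_min)

    Focal (overridden) taxa keep their current rates. Degenerate cases — a
    single taxon, all abundances equal, or ``mu_min == mu_max`` — collapse to
    ``mu_max`` for every mapped taxon.
    """
    if mu_min > mu_max:
        raise ValueError("mu_min must not exceed mu_max")
    mapped = ~pool.focal_flags
    a = pool.rel_abundance[mapped]
    if np.any(a <= 0):
        raise ValueError("cannot map growth rates for zero-abundance taxa")
    log_a = np.log10(a)
    lo, hi = log_a.min(), log_a.max()
    if hi - lo == 0 or mu_min == mu_max:
        rates_mapped = np.full(a.size, mu_max if hi - lo == 0 else mu_min)
    else:
        rates_mapped = mu_min + (mu_max - mu_min) * (log_a - lo) / (hi - lo)
    rates = pool.growth_rate.copy()
    rates[mapped] = rates_mapped
    return replace(pool, growth_rate=rates)


def set_focal_rates(pool: TaxonPool, focal_ids: list[str], rates: list[float]) -> TaxonPool:
    """Override the growth rates of named taxa and flag them as focal."""
    if len(focal_ids) != len(rates):
        raise ValueError("focal_ids and rates must have equal length")
    if len(set(focal_ids)) != len(focal_ids):
        raise ValueError("duplicate taxon id in focal_ids")
    new_rates = pool.growth_rate.copy()
    flags = pool.focal_flags.copy()
    for tid, r in zip(focal_ids, rates):
        i = pool.index_of(tid)
        new_rates[i] = float(r)
        flags[i] = True
    return replace(pool, growth_rate=new_rates, focal_flags=flags)


def sample_inoculum(pool: TaxonPool, n_cells: int = 200_000, seed: int | None = None) -> Inoculum:
    """Draw a finite inoculum of ``n_cells`` individual cells.

    Multinomial sampling weighted by the pool's relative abundances — the
    first of the two stochastic bottlenecks. Rare taxa routinely draw zero
    cells; this is the phenomenon under study, not an artefact.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_cells, pool.rel_abundance / pool.rel_abundance.sum())
    return Inoculum(counts=counts)


def simulate_batch(
    inoc: Inoculum,
    pool: TaxonPool,
    params: GrowthParams,
    *,
    s_tol_frac: float = 1e-6,
    t_max: float = 10_000.0,
    rtol: float = 1e-8,
) -> CommunityState:
    """Grow a batch until the substrate carbon is depleted.

    Integrates the shared-substrate Monod system with an adaptive solver,
    terminating when S falls below ``s_tol_frac * S0`` (or at ``t_max``).
    Taxa that start at zero cells stay at zero. Mass balance — biomass carbon
    gained equals substrate carbon consumed times the yield — holds to well
    below 0.1% relative.
    """
    n0 = inoc.counts.astype(float)
    if params.S0 == 0 or n0.sum() == 0:
        return CommunityState(counts=n0, substrate=params.S0, time=0.0)

    mu = pool.growth_rate
    k = params.c_cell / params.Y
    s_tol = s_tol_frac * params.S0

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        n, s = y[:-1], max(y[-1], 0.0)
        growth = mu * (s / (params.K_s + s)) * n
        return np.append(growth, -k * growth.sum())

    def depleted(t: float, y: np.ndarray) -> float:
        return y[-1] - s_tol

    depleted.terminal = True  # type: ignore[attr-defined]
    depleted.direction = -1  # type: ignore[attr-defined]

    y0 = np.append(n0, params.S0)
    atol = np.append(np.full(n0.size, 1e-6), s_tol * 1e-3)
    sol = solve_ivp(rhs, (0.0, t_max), y0, method="LSODA", events=depleted,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"batch integration failed: {sol.message}")
    y_end = sol.y_events[0][0] if sol.y_events[0].size else sol.y[:, -1]
    t_end = float(sol.t_events[0][0]) if sol.t_events[0].size else float(sol.t[-1])
    counts = np.maximum(y_end[:-1], 0.0)
    counts[n0 == 0] = 0.0
    substrate = max(float(y_end[-1]), 0.0)
    if not np.all(np.isfinite(counts)):
        raise RuntimeError("non-finite cell counts during batch integration")
    return CommunityState(counts=counts, substrate=substrate, time=t_end)


def subsample_counts(state: CommunityState, depth: int = 200_000, seed: int | None = None) -> Inoculum:
    """Subsample the grown community to a fixed depth, as if sequenced.

    Multinomial draw of ``depth`` reads with probabilities proportional to the
    cell counts — the second stochastic bottleneck.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    total = state.counts.sum()
    if total < depth:
        raise ValueError(f"subsampling depth {depth} exceeds community size {total:.3g}")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, state.counts / total)
    return Inoculum(counts=counts)


@dataclass(frozen=True)
class EnsembleResult:
    """Replicate ensemble output: counts matrix and stacked relative table."""

    counts: "pd.DataFrame"  # replicates x taxa, subsampled counts
    rel_abundance: "pd.DataFrame"  # long format: replicate, taxon_id, rel_abundance
    seeds: tuple[int, ...]
    final_sizes: tuple[float, ...]


def run_replicate_ensemble(
    pool: TaxonPool,
    params: GrowthParams,
    *,
    n_replicates: int = 5,
    seeds: list[int],
    n_cells: int = 200_000,
    depth: int = 200_000,
) -> EnsembleResult:
    """Run independent inoculate-grow-subsample replicates.

    Each replicate uses one seeded generator stream (seed recorded in the
    output) to draw its inoculum and its read subsample; growth in between is
    deterministic.
    """
    import pandas as pd

    if len(seeds) != n_replicates:
        raise ValueError("need exactly one seed per replicate")
    rows, final_sizes, long_rows = [], [], []
    for r, seed in enumerate(seeds):
        try:
            ss = np.random.SeedSequence(seed)
            seed_inoc, seed_sub = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
            inoc = sample_inoculum(pool, n_cells=n_cells, seed=seed_inoc)
            state = simulate_batch(inoc, pool, params)
            sub = subsample_counts(state, depth=depth, seed=seed_sub)
        except Exception as exc:
            raise RuntimeError(f"replicate {r} failed: {exc}") from exc
        rows.append(sub.counts)
        final_sizes.append(state.total)
        rel = sub.counts / sub.counts.sum()
        long_rows.extend(
            {"replicate": r, "taxon_id": tid, "rel_abundance": p}
            for tid, p in zip(pool.taxon_ids, rel)
        )
    counts = pd.DataFrame(rows, columns=list(pool.taxon_ids))
    counts.index.name = "replicate"
    return EnsembleResult(
        counts=counts,
        rel_abundance=pd.DataFrame(long_rows),
        seeds=tuple(int(s) for s in seeds),
        final_sizes=tuple(final_sizes),
    )
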