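"""Synthetic fixtures with the statistical structure the analyses assume.

Three generators, all pure functions of (parameters, seed):

* a long-tailed lognormal rank-abundance pool standing in for a measured soil
  community (~314 major taxa, most of them rare);
* amplicon read sets embedding per-strain identifier substrings at known
  proportions, with a machine-readable truth table;
* flow-cytometry event tables with separated cell and colloid-background
  populations at configurable channel means/SDs.

Reads are error-free by default: the downstream counting is exact-match, so
sequencing-error simulation is a flagged extension, not the default.
Every generator ships truth metadata so round-trip tests can close the loop.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .amplicon import IdentifierCatalog
from .growth import TaxonPool, assign_growth_rates

__all__ = [
    "make_rank_abundance",
    "make_focal_pool",
    "make_catalog",
    "make_reads",
    "write_reads_fastq",
    "make_fcm_events",
    "ReadSet",
    "FcmFixture",
]

_BASES = np.array(list("ACGT"))


def make_rank_abundance(
    n_taxa: int = 314,
    mu_log: float = 0.0,
    sigma_log: float = 2.0,
    seed: int | None = None,
    *,
    assign_rates: bool = True,
    mu_min: float = 0.01,
    mu_max: float = 0.4,
) -> TaxonPool:
    """Draw a lognormal rank-abundance distribution, sorted descending.

    ``sigma_log`` (log-space SD in natural log units) controls tail length;
    sigma ~ 2 gives a soil-like shape where most taxa sit below 1e-3 relative
    abundance. ``sigma_log = 0`` degenerates to a uniform community. Growth
    rates are mapped from abundance unless ``assign_rates`` is off (then a
    placeholder uniform rate is set).
    """
    if n_taxa < 1:
        raise ValueError("need at least one taxon")
    rng = np.random.default_rng(seed)
    draws = rng.lognormal(mean=mu_log, sigma=sigma_log, size=n_taxa)
    draws = np.sort(draws)[::-1]
    rel = draws / draws.sum()
    ids = tuple(f"t{i + 1:03d}" for i in range(n_taxa))
    pool = TaxonPool(
        taxon_ids=ids,
        rel_abundance=rel,
        growth_rate=np.full(n_taxa, mu_max),
    )
    if assign_rates and n_taxa > 1 and sigma_log > 0:
        pool = assign_growth_rates(pool, mu_min=mu_min, mu_max=mu_max)
    return pool


FOCAL_RATES = (0.55, 0.25, 0.8, 0.6, 0.35)


def make_focal_pool(
    n_taxa: int = 314,
    n_cells: int = 200_000,
    focal_expected_cells: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 3.0),
    focal_rates: tuple[float, ...] = FOCAL_RATES,
    sigma_log: float = 2.0,
    seed: int | None = None,
) -> TaxonPool:
    """Long-tailed pool with rare fast-growing focal taxa.

    Builds the stochastic-bottleneck study design: a lognormal rank-abundance
    pool whose growth rates follow the abundance map, plus a handful of rare
    taxa whose abundances are pinned so a ``n_cells``-cell inoculum draws them
    at single-digit expected counts, and whose growth rates are overridden to
    the high focal values. Returns the pool with focal taxa flagged.
    """
    from .growth import set_focal_rates

    if len(focal_expected_cells) != len(focal_rates):
        raise ValueError("need one expected inoculum count per focal rate")
    pool = make_rank_abundance(n_taxa=n_taxa, sigma_log=sigma_log, seed=seed,
                               assign_rates=False)
    rel = pool.rel_abundance.copy()
    # pin the rarest taxa to abundances giving the requested expected draws
    focal_idx = np.argsort(rel)[: len(focal_rates)]
    rel[focal_idx] = np.asarray(focal_expected_cells, dtype=float) / n_cells
    rel = rel / rel.sum()
    pool = TaxonPool(pool.taxon_ids, rel, pool.growth_rate)
    pool = assign_growth_rates(pool)
    focal_ids = [pool.taxon_ids[i] for i in focal_idx]
    return set_focal_rates(pool, focal_ids, list(focal_rates))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def make_catalog(
    n_strains: int = 21,
    identifier_lengths: tuple[int, ...] = (60, 90),
    copy_range: tuple[int, int] = (1, 7),
    seed: int | None = None,
) -> IdentifierCatalog:
    """Generate a synthetic identifier catalog (random unique 60/90-nt tags).

    Operon copy numbers are drawn uniformly from ``copy_range`` inclusive.
    Random 60-nt sequences are effectively never substrings of one another,
    but the catalog's own validation enforces it.
    """
    rng = np.random.default_rng(seed)
    idents: list[str] = []
    while len(idents) < n_strains:
        L = int(rng.choice(identifier_lengths))
        cand = _random_seq(rng, L)
        if any(cand in s or s in cand for s in idents):
            continue
        idents.append(cand)
    strain_ids = tuple(f"s{i + 1:02d}" for i in range(n_strains))
    copies = tuple(int(c) for c in rng.integers(copy_range[0], copy_range[1] + 1, size=n_strains))
    return IdentifierCatalog(strain_ids, tuple(idents), copies)


@dataclass(frozen=True)
class ReadSet:
    """Generated reads plus their ground truth."""

    reads: tuple[str, ...]
    truth_counts: dict[str, int]  # strain_id -> reads embedding its identifier
    proportions: dict[str, float]


def make_reads(
    catalog: IdentifierCatalog,
    proportions: dict[str, float],
    n_reads: int = 10_000,
    read_length: int = 250,
    seed: int | None = None,
) -> ReadSet:
    """Generate reads each embedding exactly one strain's identifier.

    The strain per read is drawn multinomially from ``proportions``; the
    identifier is placed at a random offset inside random background sequence.
    Backgrounds are rejection-checked so no read accidentally contains a
    second catalog identifier.
    """
    props = np.array([proportions.get(s, 0.0) for s in catalog.strain_ids], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1 over catalog strains")
    max_len = max(len(s) for s in catalog.identifiers)
    if read_length < max_len:
        raise ValueError(f"read_length {read_length} shorter than longest identifier ({max_len})")
    rng = np.random.default_rng(seed)
    per_strain = rng.multinomial(n_reads, props)
    reads: list[str] = []
    for i, (sid, ident) in enumerate(zip(catalog.strain_ids, catalog.identifiers)):
        for _ in range(per_strain[i]):
            while True:
                offset = int(rng.integers(0, read_length - len(ident) + 1))
                pre = _random_seq(rng, offset)
                post = _random_seq(rng, read_length - len(ident) - offset)
                read = pre + ident + post
                # reject chance occurrences of any other identifier, or a
                # spurious second copy of this one
                hits = sum(read.count(x) for x in catalog.identifiers)
                if hits == 1:
                    reads.append(read)
                    break
    order = rng.permutation(len(reads))
    reads = [reads[j] for j in order]
    truth = {sid: int(c) for sid, c in zip(catalog.strain_ids, per_strain)}
    return ReadSet(reads=tuple(reads), truth_counts=truth,
                   proportions={s: float(p) for s, p in zip(catalog.strain_ids, props)})


def write_reads_fastq(readset: ReadSet, fastq_path: str | Path, truth_path: str | Path | None = None) -> None:
    """Write a ReadSet as plain FASTQ (uniform quality) plus a JSON truth file."""
    fastq_path = Path(fastq_path)
    with open(fastq_path, "w") as fh:
        for i, read in enumerate(readset.reads):
            fh.write(f"@read{i}\n{read}\n+\n{'I' * len(read)}\n")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump({"truth_counts": readset.truth_counts,
                       "proportions": readset.proportions}, fh, indent=1)


@dataclass(frozen=True)
class FcmFixture:
    """Synthetic event table plus truth counts and expected misclassification."""

    events: pd.DataFrame
    n_cells: int
    n_background: int
    expected_misclassification: dict[str, float]


def make_fcm_events(
    n_cells: int = 1000,
    n_background: int = 500,
    cell_means: tuple[float, float] = (200.0, 1500.0),
    cell_sds: tuple[float, float] = (30.0, 200.0),
    background_means: tuple[float, float] = (20.0, 100.0),
    background_sds: tuple[float, float] = (8.0, 40.0),
    gate: tuple[float, float] = (50.0, 350.0),
    strict: bool = True,
    seed: int | None = None,
) -> FcmFixture:
    """Generate a two-population FCM event table (cells vs colloid background).

    Channel values (FSC-H, FITC-H) are normal draws per population. With
    ``strict`` (default) cell draws are clamped strictly above the gate and
    background draws strictly below, so the gated count equals ``n_cells``
    exactly; without it, the expected misclassification rates from the normal
    CDF are reported in the fixture metadata.
    """
    if not (cell_means[0] > gate[0] and cell_means[1] > gate[1]):
        raise ValueError("cell channel means must lie above the gate thresholds")
    if not (background_means[0] < gate[0] or background_means[1] < gate[1]):
        raise ValueError("background means must lie below the gate in at least one channel")
    rng = np.random.default_rng(seed)
    cf, ci = (rng.normal(cell_means[k], cell_sds[k], n_cells) for k in (0, 1))
    bf, bi = (rng.normal(background_means[k], background_sds[k], n_background) for k in (0, 1))
    if strict:
        eps = 1e-9
        cf = np.maximum(cf, gate[0] + eps)
        ci = np.maximum(ci, gate[1] + eps)
        bf = np.minimum(bf, gate[0])
        bi = np.minimum(bi, gate[1])
    # miss: a true cell falling below either gate; false positive: background above both
    p_cell_miss = 0.0 if strict else float(
        1 - norm.sf(gate[0], cell_means[0], cell_sds[0]) * norm.sf(gate[1], cell_means[1], cell_sds[1])
    )
    p_bg_pass = 0.0 if strict else float(
        norm.sf(gate[0], background_means[0], background_sds[0])
        * norm.sf(gate[1], background_means[1], background_sds[1])
    )
    events = pd.DataFrame(
        {
            "FSC-H": np.concatenate([cf, bf]),
            "FITC-H": np.concatenate([ci, bi]),
            "population": ["cell"] * n_cells + ["background"] * n_background,
        }
    )
    events = events.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(drop=True)
    return FcmFixture(
        events=events,
        n_cells=n_cells,
        n_background=n_background,
        expected_misclassification={"cell_miss": p_cell_miss, "background_pass": p_bg_pass},
    )
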