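"""Plain-text I/O: abundance tables, community matrices, run metadata.

All interchange formats are simple TSV/JSON so outputs can be inspected and
fed straight into external stats environments (the package exports distance
matrices rather than reimplementing ordination or permutation tests).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .growth import TaxonPool

__all__ = [
    "read_abundance_tsv",
    "write_pool_tsv",
    "read_community_matrix",
    "write_community_matrix",
    "write_metadata",
]


def read_abundance_tsv(path: str | Path, default_rate: float = 0.4) -> TaxonPool:
    """Load a TaxonPool from TSV columns taxon_id, rel_abundance [, growth_rate].

    Abundances are renormalised to sum to exactly 1. Without a growth_rate
    column every taxon gets ``default_rate`` (map rates afterwards with
    :func:`soilcosm.growth.assign_growth_rates`).
    """
    df = pd.read_csv(path, sep="\t", dtype={"taxon_id": str})
    if not {"taxon_id", "rel_abundance"} <= set(df.columns):
        raise ValueError(f"{path}: need columns taxon_id, rel_abundance")
    rel = df["rel_abundance"].to_numpy(dtype=float)
    if rel.sum() <= 0:
        raise ValueError(f"{path}: abundances sum to zero")
    rel = rel / rel.sum()
    rates = (
        df["growth_rate"].to_numpy(dtype=float)
        if "growth_rate" in df.columns
        else np.full(len(df), default_rate)
    )
    return TaxonPool(tuple(df["taxon_id"]), rel, rates)


def write_pool_tsv(pool: TaxonPool, path: str | Path) -> None:
    pd.DataFrame(
        {
            "taxon_id": pool.taxon_ids,
            "rel_abundance": pool.rel_abundance,
            "growth_rate": pool.growth_rate,
            "focal": pool.focal_flags.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


_META_COLS = ("replicate", "cycle", "regime", "group")


def read_community_matrix(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a sample-by-taxon TSV; returns (abundances, metadata columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_cols = [c for c in df.columns if c in _META_COLS]
    return df.drop(columns=meta_cols), df[meta_cols]


def write_community_matrix(
    m: pd.DataFrame, path: str | Path, metadata: pd.DataFrame | None = None
) -> None:
    out = m if metadata is None else pd.concat([metadata, m], axis=1)
    out.to_csv(path, sep="\t")


def write_metadata(path: str | Path, **fields) -> None:
    """Write a run-metadata JSON (config echo, seeds, package version)."""
    from . import __version__

    payload = {"package": "soilcosm", "version": __version__, **fields}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
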