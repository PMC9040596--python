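"""Identifier-based SynCom strain quantification from amplicon reads.

Each of the community's strains carries a unique 60- or 90-nt variable region
of its 16S rRNA gene that serves as an exact-match identifier. Quantification
is deliberately simple: a read is assigned to a strain iff that strain's
identifier occurs verbatim (forward strand) in the read. Raw per-strain read
counts are then divided by each strain's 16S rRNA operon copy number — so
counts reflect cells rather than gene copies — normalised to relative
abundances, and optionally anchored to an absolute scale using a
flow-cytometry total cell density.

Reads matching two or more identifiers are ambiguous and excluded from all
counts (the exclusion is logged); reads matching none are simply unclassified.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "IdentifierCatalog",
    "StrainCountTable",
    "count_identifiers",
    "correct_and_normalize",
    "absolute_abundance",
    "read_catalog",
    "iter_reads",
    "select_identifiers",
]


@dataclass(frozen=True)
class IdentifierCatalog:
    """Per-strain identifier sequences and 16S operon copy numbers."""

    strain_ids: tuple[str, ...]
    identifiers: tuple[str, ...]
    operon_copies: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.strain_ids:
            raise ValueError("catalog must contain at least one strain")
        if not (len(self.strain_ids) == len(self.identifiers) == len(self.operon_copies)):
            raise ValueError("catalog fields must have equal length")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise ValueError("strain ids must be unique")
        idents = tuple(s.upper() for s in self.identifiers)
        object.__setattr__(self, "identifiers", idents)
        for s in idents:
            if set(s) - set("ACGT"):
                raise ValueError(f"identifier contains non-ACGT characters: {s[:20]}...")
        for i, a in enumerate(idents):
            for j, b in enumerate(idents):
                if i != j and a in b:
                    raise ValueError(
                        f"identifier of {self.strain_ids[i]} is contained in "
                        f"that of {self.strain_ids[j]}"
                    )
        if any(c < 1 for c in self.operon_copies):
            raise ValueError("operon copy numbers must be positive integers")

    def __len__(self) -> int:
        return len(self.strain_ids)


@dataclass(frozen=True)
class StrainCountTable:
    """Raw → operon-corrected → relative → absolute strain abundances."""

    table: pd.DataFrame  # index: strain_id; columns: raw_count, corrected_count, rel_abundance [, abs_abundance]
    n_classified: int
    n_ambiguous: int = 0

    @property
    def empty(self) -> bool:
        """True when no reads were assigned to any strain."""
        return self.table["raw_count"].sum() == 0


def iter_reads(path: str | Path) -> Iterator[str]:
    """Yield uppercase read sequences from FASTA/FASTQ, gzipped or plain."""
    path = Path(path)
    name = path.name.lower()
    fmt = "fastq" if name.removesuffix(".gz").rsplit(".", 1)[-1] in ("fastq", "fq") else "fasta"
    opener = gzip.open if name.endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield str(rec.seq).upper()


def read_catalog(fasta_path: str | Path, copies_tsv: str | Path) -> IdentifierCatalog:
    """Load an identifier catalog from FASTA (identifiers) + TSV (strain_id, operon_copies)."""
    copies = pd.read_csv(copies_tsv, sep="\t", dtype={"strain_id": str})
    copy_map = dict(zip(copies["strain_id"], copies["operon_copies"].astype(int)))
    ids, seqs, ncopies = [], [], []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in copy_map:
            raise ValueError(f"strain {rec.id!r} has no operon copy number in {copies_tsv}")
        ids.append(rec.id)
        seqs.append(str(rec.seq))
        ncopies.append(copy_map[rec.id])
    return IdentifierCatalog(tuple(ids), tuple(seqs), tuple(ncopies))


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def count_identifiers(
    reads: Iterable[str],
    catalog: IdentifierCatalog,
    *,
    search_revcomp: bool = False,
) -> tuple[np.ndarray, int]:
    """Count reads containing each strain's identifier as an exact substring.

    A read increments exactly one strain's count; reads hitting two or more
    identifiers are excluded as ambiguous. Matching is exact and forward-strand
    by default (reverse-complement search can be enabled).

    Returns (raw counts aligned to the catalog, number of ambiguous reads).
    """
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    idents = catalog.identifiers
    rc = tuple(_revcomp(s) for s in idents) if search_revcomp else None
    counts = np.zeros(len(idents), dtype=np.int64)
    n_ambiguous = 0
    for read in reads:
        read = read.upper()
        hit = -1
        ambiguous = False
        for i, ident in enumerate(idents):
            if ident in read or (rc is not None and rc[i] in read):
                if hit >= 0:
                    ambiguous = True
                    break
                hit = i
        if ambiguous:
            n_ambiguous += 1
        elif hit >= 0:
            counts[hit] += 1
    if n_ambiguous:
        logger.warning("excluded %d ambiguous reads matching multiple identifiers", n_ambiguous)
    return counts, n_ambiguous


def correct_and_normalize(
    raw: np.ndarray | Iterable[int],
    catalog: IdentifierCatalog,
    n_classified: int | None = None,
    n_ambiguous: int = 0,
) -> StrainCountTable:
    """Divide raw counts by operon copies and normalise to relative abundances.

    ``corrected_i = raw_i / copies_i`` and ``rel_i = corrected_i / sum(corrected)``.
    ``n_classified`` defaults to the raw-count total. An all-zero input yields
    an explicit empty-community table (relative abundances all zero).
    """
    raw = np.asarray(list(raw) if not isinstance(raw, np.ndarray) else raw, dtype=float)
    if raw.size != len(catalog):
        raise ValueError("raw counts not aligned to catalog")
    if np.any(raw < 0):
        raise ValueError("raw counts must be non-negative")
    total_raw = raw.sum()
    if n_classified is None:
        n_classified = int(total_raw)
    if n_classified < total_raw:
        raise ValueError("n_classified cannot be smaller than the summed raw counts")
    copies = np.asarray(catalog.operon_copies, dtype=float)
    corrected = raw / copies
    denom = corrected.sum()
    rel = corrected / denom if denom > 0 else np.zeros_like(corrected)
    table = pd.DataFrame(
        {
            "raw_count": raw.astype(np.int64),
            "corrected_count": corrected,
            "rel_abundance": rel,
        },
        index=pd.Index(catalog.strain_ids, name="strain_id"),
    )
    return StrainCountTable(table=table, n_classified=n_classified, n_ambiguous=n_ambiguous)


def absolute_abundance(table: StrainCountTable, total_cells_per_ml: float) -> StrainCountTable:
    """Anchor relative abundances to a flow-cytometry total community size.

    abs_i = rel_i * total_cells_per_ml; the per-strain absolute abundances sum
    to the supplied total.
    """
    if total_cells_per_ml < 0:
        raise ValueError("total cell density must be non-negative")
    out = table.table.copy()
    out["abs_abundance"] = out["rel_abundance"] * total_cells_per_ml
    return StrainCountTable(table=out, n_classified=table.n_classified,
                            n_ambiguous=table.n_ambiguous)


def select_identifiers(
    sequences: dict[str, str],
    lengths: tuple[int, ...] = (60, 90),
) -> dict[str, str]:
    """Pick, per strain, a shortest window unique across all strains' genes.

    Utility for building a catalog from aligned marker genes: for each strain,
    scan windows of the candidate lengths (shortest first) and return the
    first window that occurs in no other strain's sequence. Raises if a strain
    has no unique window at any candidate length.
    """
    chosen: dict[str, str] = {}
    for sid, seq in sequences.items():
        seq = seq.upper()
        others = [s.upper() for k, s in sequences.items() if k != sid]
        found = None
        for L in sorted(lengths):
            for start in range(0, len(seq) - L + 1):
                window = seq[start:start + L]
                if not any(window in o for o in others):
                    found = window
                    break
            if found:
                break
        if found is None:
            raise ValueError(f"no unique identifier window found for strain {sid!r}")
        chosen[sid] = found
    return chosen
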