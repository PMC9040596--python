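"""Flow-cytometry cell counting: threshold gating and background subtraction.

Stained-cell events are gated on forward scatter and SYBR-green fluorescence
(strictly FSC-H > 50 and FITC-H > 350 by default, calibrated against buffer
controls). Uninoculated blanks quantify colloidal background, whose gated
count is subtracted before converting to cells per mL with dilution
correction. Input is plain CSV with FSC-H / FITC-H columns; instrument file
formats are out of scope.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_FSC_MIN", "DEFAULT_FITC_MIN", "gate_events", "cells_per_ml",
           "load_events", "process_sample_sheet"]

DEFAULT_FSC_MIN = 50.0
DEFAULT_FITC_MIN = 350.0


def load_events(path: str | Path) -> pd.DataFrame:
    """Read an event table CSV; requires FSC-H and FITC-H columns."""
    df = pd.read_csv(path)
    missing = {"FSC-H", "FITC-H"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def gate_events(
    events: pd.DataFrame,
    fsc_min: float = DEFAULT_FSC_MIN,
    fitc_min: float = DEFAULT_FITC_MIN,
) -> int:
    """Count events passing the cell gate: FSC-H > fsc_min AND FITC-H > fitc_min (strict)."""
    if events.empty:
        return 0
    passed = (events["FSC-H"] > fsc_min) & (events["FITC-H"] > fitc_min)
    return int(passed.sum())


def cells_per_ml(
    gated: int,
    blank_gated: int = 0,
    volume_ul: float = 20.0,
    dilution: float = 1.0,
) -> float:
    """Convert a background-subtracted gated count to cells per mL.

    density = max(gated - blank_gated, 0) / (volume_ul * 1e-3 mL) * dilution

    The blank is subtracted on gated counts at matched acquisition volume and
    dilution. A blank exceeding the sample clips to zero with a warning.
    """
    if volume_ul <= 0:
        raise ValueError("acquisition volume must be positive")
    if dilution < 1:
        raise ValueError("dilution factor must be at least 1")
    net = gated - blank_gated
    if net < 0:
        logger.warning("blank gated count (%d) exceeds sample (%d); clipping to 0",
                       blank_gated, gated)
        net = 0
    return net / (volume_ul * 1e-3) * dilution


def process_sample_sheet(
    sheet: pd.DataFrame,
    event_dir: str | Path,
    fsc_min: float = DEFAULT_FSC_MIN,
    fitc_min: float = DEFAULT_FITC_MIN,
) -> pd.DataFrame:
    """Gate and quantify a batch of samples with per-sample blank pairing.

    ``sheet`` columns: sample_id, blank_id, volume_ul, dilution. Event CSVs are
    looked up as ``<event_dir>/<id>.csv``. Returns a table with gated counts,
    blank counts and cell densities.
    """
    event_dir = Path(event_dir)
    blank_cache: dict[str, int] = {}
    rows = []
    for rec in sheet.itertuples(index=False):
        gated = gate_events(load_events(event_dir / f"{rec.sample_id}.csv"), fsc_min, fitc_min)
        blank_id = getattr(rec, "blank_id", "")
        if not isinstance(blank_id, str):  # NaN from an empty TSV cell
            blank_id = ""
        if blank_id and blank_id not in blank_cache:
            blank_cache[blank_id] = gate_events(
                load_events(event_dir / f"{blank_id}.csv"), fsc_min, fitc_min
            )
        blank = blank_cache.get(blank_id, 0)
        rows.append(
            {
                "sample_id": rec.sample_id,
                "gated": gated,
                "blank_gated": blank,
                "cells_per_ml": cells_per_ml(gated, blank, rec.volume_ul, rec.dilution),
            }
        )
    return pd.DataFrame(rows)
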