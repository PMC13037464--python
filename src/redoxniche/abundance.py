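"""Microscopy filter counts to volumetric abundances, and host division.

Host ciliates are counted by FISH on a known fraction of a polycarbonate
filter through which a known water volume was passed (the field protocol:
1/16 filter sections, 500 ml fixed lake water).  The count extrapolates to
cells per litre as ``counted / section_fraction / filtered_volume``.
Dividing cells (elongated cell body and macronucleus) give a scale-free
dividing fraction, and symbiont counts in daughter-cell pairs summarise
how evenly the endosymbiont population is partitioned at host division.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError

#: abundances are reported per litre; multiply by this for per-m³
CELLS_PER_L_TO_PER_M3 = 1000.0


@dataclass
class FilterCountRecord:
    """One microscopy count plus the geometry to convert it to cells/l."""

    depth: float
    counted: int
    section_fraction: float
    filtered_volume: float
    dividing_counted: int = 0

    def __post_init__(self) -> None:
        if self.counted < 0:
            raise ValidationError("counted >= 0 violated")
        if not 0 <= self.dividing_counted <= self.counted:
            raise ValidationError("counted >= dividing_counted >= 0 violated")
        if not 0 < self.section_fraction <= 1:
            raise ParameterError("0 < section_fraction <= 1 violated")
        if self.filtered_volume <= 0:
            raise ParameterError("filtered_volume > 0 violated")


@dataclass
class SymbiontPartition:
    """Endosymbiont counts in the two daughter cells of one division."""

    daughter_a: int
    daughter_b: int

    def __post_init__(self) -> None:
        if self.daughter_a < 0 or self.daughter_b < 0:
            raise ValidationError("symbiont counts must be >= 0")


@dataclass
class PartitionSummary:
    mean_a: float
    mean_b: float
    mean_total: float
    #: mean of |a-b|/(a+b) over pairs with a+b > 0; None if no such pair
    asymmetry_index: Optional[float]


def extrapolate_abundance(record: FilterCountRecord) -> float:
    """Cells per litre from one filter-section count.

    ``counted / section_fraction / filtered_volume``, evaluated in exact
    rational arithmetic before the final float conversion (section
    fractions such as 1/16 divide out exactly).
    """
    result = (
        Fraction(record.counted)
        / Fraction(record.section_fraction)
        / Fraction(record.filtered_volume)
    )
    return float(result)


def dividing_fraction(record: FilterCountRecord) -> Optional[float]:
    """Fraction of counted cells in division; ``None`` when nothing was
    counted (undefined, not zero)."""
    if record.counted == 0:
        return None
    return record.dividing_counted / record.counted


def partition_summary(partitions: Sequence[SymbiontPartition]) -> PartitionSummary:
    """Summarise symbiont partitioning over daughter-cell pairs.

    Daughters are kept as labelled (no re-sorting within pairs).  The
    asymmetry index averages ``|a - b| / (a + b)`` over pairs with at
    least one symbiont; it is 0 iff every such pair is equal.
    """
    if not partitions:
        raise ValidationError("empty partition list")
    a = np.array([p.daughter_a for p in partitions], dtype=float)
    b = np.array([p.daughter_b for p in partitions], dtype=float)
    tot = a + b
    nonzero = tot > 0
    asym = (
        float(np.mean(np.abs(a - b)[nonzero] / tot[nonzero]))
        if nonzero.any()
        else None
    )
    return PartitionSummary(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        mean_total=float(tot.mean()),
        asymmetry_index=asym,
    )


# ---------------------------------------------------------------------------
# delimited-text interface
# ---------------------------------------------------------------------------

COUNT_COLUMNS = [
    "depth_m",
    "counted",
    "dividing_counted",
    "section_fraction",
    "filtered_volume_l",
]


def records_to_frame(records: Sequence[FilterCountRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "depth_m": [r.depth for r in records],
            "counted": [r.counted for r in records],
            "dividing_counted": [r.dividing_counted for r in records],
            "section_fraction": [r.section_fraction for r in records],
            "filtered_volume_l": [r.filtered_volume for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[FilterCountRecord]:
    missing = [c for c in COUNT_COLUMNS if c not in df.columns and c != "dividing_counted"]
    if missing:
        raise ValidationError(f"count table missing column(s) {missing}")
    return [
        FilterCountRecord(
            depth=float(row["depth_m"]),
            counted=int(row["counted"]),
            section_fraction=float(row["section_fraction"]),
            filtered_volume=float(row["filtered_volume_l"]),
            dividing_counted=int(row.get("dividing_counted", 0) or 0),
        )
        for _, row in df.iterrows()
    ]


def extrapolate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Append ``abundance_cells_per_l`` (and ``dividing_fraction`` when
    dividing counts are present) to a count table."""
    records = frame_to_records(df)
    out = df.copy()
    out["abundance_cells_per_l"] = [extrapolate_abundance(r) for r in records]
    if "dividing_counted" in df.columns:
        out["dividing_fraction"] = [
            f if (f := dividing_fraction(r)) is not None else np.nan
            for r in records
        ]
    return out
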