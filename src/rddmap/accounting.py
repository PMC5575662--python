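"""Library-level read accounting (the summary-table view of a sequencing run).

For each library the block reports total reads after trimming, reads mapped
to the nuclear chromosomes, reads mapped to the organellar (chloroplast +
mitochondrial) genomes, and the overall mapped percentage.  Percentages are
printed to integer precision, except values below 1 % which keep one
decimal — matching how such tables are conventionally rounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = ["LibraryCounts", "format_percent", "library_accounting", "accounting_text"]


@dataclass
class LibraryCounts:
    """Raw read counts for one library."""

    total_reads: int
    nuclear_mapped: int
    organellar_mapped: int

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if self.nuclear_mapped + self.organellar_mapped > self.total_reads:
            raise ValueError("mapped reads exceed total reads")


def format_percent(x: float) -> str:
    """Integer precision, one decimal below 1 % (e.g. 84.25 -> '84', 0.27 -> '0.3')."""
    if x < 0:
        raise ValueError("negative percentage")
    return f"{x:.1f}" if x < 1 else f"{x:.0f}"


def library_accounting(libraries: Mapping[str, LibraryCounts]) -> pd.DataFrame:
    """Percentage table over libraries.

    Columns: raw counts, exact percentages (``pct_*``) and their printed
    forms (``pct_*_str``).  The mapped percentage is (nuclear + organellar)
    over total.
    """
    rows = {}
    for name, c in libraries.items():
        pct_nuc = 100.0 * c.nuclear_mapped / c.total_reads
        pct_org = 100.0 * c.organellar_mapped / c.total_reads
        pct_map = 100.0 * (c.nuclear_mapped + c.organellar_mapped) / c.total_reads
        rows[name] = {
            "total_reads": c.total_reads,
            "nuclear_mapped": c.nuclear_mapped,
            "organellar_mapped": c.organellar_mapped,
            "pct_nuclear": pct_nuc,
            "pct_organellar": pct_org,
            "pct_mapped": pct_map,
            "pct_nuclear_str": format_percent(pct_nuc),
            "pct_organellar_str": format_percent(pct_org),
            "pct_mapped_str": format_percent(pct_map),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def accounting_text(table: pd.DataFrame) -> str:
    """Human-readable read-accounting block."""
    lines = ["Read accounting", "---------------"]
    for name, row in table.iterrows():
        lines.append(
            f"{name}: {int(row.total_reads):,} reads after trim; "
            f"{int(row.nuclear_mapped):,} ({row.pct_nuclear_str}%) nuclear; "
            f"{int(row.organellar_mapped):,} ({row.pct_organellar_str}%) organellar; "
            f"{row.pct_mapped_str}% mapped"
        )
    return "\n".join(lines)
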