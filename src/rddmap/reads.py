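"""Read-level filters applied to alignment records before any counting.

Three steps, in any order (the filters commute):

* a length filter dropping post-trim reads shorter than 30 nt, which keeps
  the 24-nt siRNA fraction out of the lncRNA analysis;
* an alignment acceptance filter (identity >= 80 % over >= 70 % of the read,
  at most 20 genomic placements — multi-mappers are retained deliberately so
  repeat-derived RNA is not discarded);
* a global strand flip, because template-switch library construction
  sequences the strand opposite to the RNA actually bound.

All thresholds are inclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace
from typing import Sequence

from .model import AlignedRead, Strand

__all__ = ["length_filter", "acceptance_filter", "orient_reads"]

log = logging.getLogger(__name__)


def length_filter(reads: Sequence[AlignedRead], min_read_len: int) -> list[AlignedRead]:
    """Retain reads with ``read_length >= min_read_len``."""
    kept = [r for r in reads if r.read_length >= min_read_len]
    removed = len(reads) - len(kept)
    if removed:
        log.info("length_filter: removed %d/%d reads (< %d nt)",
                 removed, len(reads), min_read_len)
    return kept


def acceptance_filter(
    reads: Sequence[AlignedRead],
    min_identity: float,
    min_aligned_fraction: float,
    max_hits: int,
) -> list[AlignedRead]:
    """Retain reads meeting all three mapping acceptance thresholds.

    Boundary values pass: identity exactly ``min_identity``, aligned fraction
    exactly ``min_aligned_fraction`` and ``n_hits`` exactly ``max_hits`` are
    all kept.
    """
    for r in reads:
        if r.identity is None or r.aligned_fraction is None or r.n_hits is None:
            raise ValueError(f"read {r.read_id}: missing alignment attributes")
    kept = [
        r
        for r in reads
        if r.identity >= min_identity
        and r.aligned_fraction >= min_aligned_fraction
        and r.n_hits <= max_hits
    ]
    removed = len(reads) - len(kept)
    if removed:
        log.info("acceptance_filter: removed %d/%d reads", removed, len(reads))
    return kept


def orient_reads(reads: Sequence[AlignedRead]) -> list[AlignedRead]:
    """Flip every read's strand (+ <-> -); coordinates are untouched.

    Applying the function twice is the identity.  Unstranded reads are left
    unchanged with a warning.
    """
    out: list[AlignedRead] = []
    n_unstranded = 0
    for r in reads:
        if r.placement.strand is Strand.UNSTRANDED:
            n_unstranded += 1
            out.append(r)
        else:
            out.append(
                replace(r, placement=replace(r.placement, strand=r.placement.strand.flipped()))
            )
    if n_unstranded:
        warnings.warn(f"orient_reads: {n_unstranded} unstranded reads left unchanged")
    return out
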