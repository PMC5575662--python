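"""Merged-interval arithmetic shared by the allocation, locus and simulation
modules.

A :class:`MergedIntervals` stores, per chromosome, the union of a set of
intervals as sorted disjoint ``(start, end)`` arrays, supporting point
membership, interval overlap and complement via binary search.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import GenomicInterval


class MergedIntervals:
    """Union of intervals, queryable by point or interval."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        for chrom, spans in by_chrom.items():
            spans.sort()
            merged: list[tuple[int, int]] = []
            for s, e in spans:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            arr = np.asarray(merged, dtype=np.int64)
            self.starts[chrom] = arr[:, 0]
            self.ends[chrom] = arr[:, 1]

    def contains(self, chrom: str, pos: int) -> bool:
        starts = self.starts.get(chrom)
        if starts is None:
            return False
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < self.ends[chrom][i]

    def contains_many(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized point membership for positions on one chromosome."""
        starts = self.starts.get(chrom)
        if starts is None:
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(positions), dtype=bool)
        out[ok] = positions[ok] < self.ends[chrom][idx[ok]]
        return out

    def overlaps_interval(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) shares >= 1 base with the union."""
        starts = self.starts.get(chrom)
        if starts is None:
            return False
        i = int(np.searchsorted(starts, end, side="left")) - 1
        return i >= 0 and self.ends[chrom][i] > start

    def coverage(self) -> int:
        return int(
            sum((self.ends[c] - self.starts[c]).sum() for c in self.starts)
        )

    def to_intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom in sorted(self.starts):
            for s, e in zip(self.starts[chrom], self.ends[chrom]):
                out.append(GenomicInterval(chrom, int(s), int(e)))
        return out


def complement_intervals(
    intervals: Sequence[GenomicInterval], lengths: Mapping[str, int]
) -> list[GenomicInterval]:
    """Intervals covering every base of ``lengths`` not covered by the input."""
    merged = MergedIntervals(intervals)
    out: list[GenomicInterval] = []
    for chrom, length in lengths.items():
        cursor = 0
        for s, e in zip(
            merged.starts.get(chrom, np.empty(0, dtype=np.int64)),
            merged.ends.get(chrom, np.empty(0, dtype=np.int64)),
        ):
            s, e = int(s), int(e)
            if s > cursor:
                out.append(GenomicInterval(chrom, cursor, min(s, length)))
            cursor = max(cursor, e)
            if cursor >= length:
                break
        if cursor < length:
            out.append(GenomicInterval(chrom, cursor, length))
    return out


def subtract_span(
    span: tuple[int, int], blockers: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """``span`` minus a sorted disjoint list of blocking spans."""
    s, e = span
    pieces: list[tuple[int, int]] = []
    cursor = s
    for bs, be in blockers:
        if be <= cursor or bs >= e:
            continue
        if bs > cursor:
            pieces.append((cursor, min(bs, e)))
        cursor = max(cursor, be)
        if cursor >= e:
            break
    if cursor < e:
        pieces.append((cursor, e))
    return pieces
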