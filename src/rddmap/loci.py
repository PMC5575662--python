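"""lncRNA locus assembly, interval-overlap statistics and sRNA mapping.

Read coverage is condensed into "coverage islands": maximal runs of reads in
which consecutive placements are separated by at most ``max_gap`` bases.
Islands supported by enough reads become loci, which can be extended and
intersected with external interval sets (ChIP peaks, transposons,
hypomethylated regions).  Significance of an observed overlap fraction is
assessed against a randomization null that re-places intervals of the same
sizes uniformly on the genome.  Small RNAs are mapped onto locus sequences
by ungapped Hamming matching of the sRNA or its reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._intervals import MergedIntervals
from .model import AlignedRead, GenomicInterval

__all__ = [
    "LncRNALocus",
    "OverlapResult",
    "assemble_loci",
    "extend_loci",
    "overlap_fraction",
    "random_interval_null",
    "map_srnas",
]


@dataclass
class LncRNALocus:
    """A read-supported genomic region producing AGO4-associated lncRNA."""

    interval: GenomicInterval
    n_reads: int

    @property
    def mean_coverage(self) -> float:
        """Mean read depth: total read-base yield over the locus length."""
        return self._read_bases / len(self.interval) if len(self.interval) else 0.0

    _read_bases: int = 0


@dataclass
class OverlapResult:
    """Observed overlap fraction with its randomization null distribution."""

    fraction_observed: float
    null_fractions: np.ndarray
    n_query: int
    n_subject: int

    @property
    def empirical_p(self) -> float:
        """(1 + #{null >= observed}) / (n_reps + 1); never exactly zero."""
        n = len(self.null_fractions)
        return (1 + int((self.null_fractions >= self.fraction_observed).sum())) / (n + 1)


def assemble_loci(
    reads: Sequence[AlignedRead], max_gap: int = 50, min_reads: int = 2
) -> list[LncRNALocus]:
    """Single-linkage assembly of read placements into coverage islands.

    Two reads belong to the same island when the gap between their intervals
    is at most ``max_gap`` (overlapping or abutting reads always merge).
    Islands with fewer than ``min_reads`` supporting reads are dropped.  The
    result is independent of input read order.
    """
    placements = sorted(
        (r.placement for r in reads), key=lambda iv: (iv.chrom, iv.start, iv.end)
    )
    loci: list[LncRNALocus] = []
    cur: list[GenomicInterval] = []
    cur_end = None

    def flush() -> None:
        if len(cur) >= min_reads:
            locus = LncRNALocus(
                interval=GenomicInterval(
                    cur[0].chrom, cur[0].start, max(iv.end for iv in cur)
                ),
                n_reads=len(cur),
            )
            locus._read_bases = sum(len(iv) for iv in cur)
            loci.append(locus)

    for iv in placements:
        if cur and iv.chrom == cur[0].chrom and iv.start - cur_end <= max_gap:
            cur.append(iv)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                flush()
            cur = [iv]
            cur_end = iv.end
    if cur:
        flush()
    return loci


def extend_loci(
    loci: Sequence[LncRNALocus],
    extension: int,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[LncRNALocus]:
    """Grow each locus by ``extension`` bp on both sides (clipped; not merged)."""
    if extension < 0:
        raise ValueError("extension must be >= 0")
    out = []
    for locus in loci:
        iv = locus.interval
        start = max(0, iv.start - extension)
        end = iv.end + extension
        if chrom_lengths is not None and iv.chrom in chrom_lengths:
            end = min(end, chrom_lengths[iv.chrom])
        extended = LncRNALocus(
            interval=GenomicInterval(iv.chrom, start, end, iv.strand),
            n_reads=locus.n_reads,
        )
        extended._read_bases = locus._read_bases
        out.append(extended)
    return out


def overlap_fraction(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> float:
    """Fraction of query intervals sharing >= 1 base with any subject interval."""
    if not query:
        raise ValueError("overlap fraction undefined for an empty query set")
    if not subject:
        return 0.0
    merged = MergedIntervals(subject)
    hits = sum(
        merged.overlaps_interval(iv.chrom, iv.start, iv.end) for iv in query
    )
    return hits / len(query)


def random_interval_null(
    query_sizes: Sequence[int],
    genome_lengths: Mapping[str, int],
    subject_intervals: Sequence[GenomicInterval],
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
    observed: float | None = None,
) -> OverlapResult:
    """Null distribution of overlap for size-matched random intervals.

    Each replicate places intervals of exactly the query's lengths uniformly
    at random: chromosome chosen proportional to its length, start uniform
    such that the interval fits without clipping; then the overlap fraction
    against ``subject_intervals`` is recorded.  ``observed`` defaults to 0
    when not supplied (callers normally pass the real query's fraction).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    sizes = np.asarray(query_sizes, dtype=np.int64)
    chroms = list(genome_lengths)
    lengths = np.asarray([genome_lengths[c] for c in chroms], dtype=np.int64)
    if sizes.max() > lengths.max():
        raise ValueError(
            f"query interval of {sizes.max()} bp exceeds every chromosome"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    merged = MergedIntervals(subject_intervals) if subject_intervals else None
    probs = lengths / lengths.sum()
    null = np.empty(n_reps, dtype=float)
    for rep in range(n_reps):
        hits = 0
        chrom_idx = rng.choice(len(chroms), size=len(sizes), p=probs)
        for size, ci in zip(sizes, chrom_idx):
            clen = lengths[ci]
            while clen < size:  # resample: interval must fit its chromosome
                ci = rng.choice(len(chroms), p=probs)
                clen = lengths[ci]
            start = int(rng.integers(0, clen - size + 1))
            if merged is not None and merged.overlaps_interval(
                chroms[ci], start, start + size
            ):
                hits += 1
        null[rep] = hits / len(sizes)
    return OverlapResult(
        fraction_observed=0.0 if observed is None else observed,
        null_fractions=null,
        n_query=len(sizes),
        n_subject=len(subject_intervals),
    )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_ODD_BITS = np.uint64(0x5555555555555555)


def _pack_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit packing of every length-k window of a base-code array."""
    n_windows = len(codes) - k + 1
    packed = np.zeros(n_windows, dtype=np.uint64)
    for j in range(k):
        packed |= codes[j : j + n_windows].astype(np.uint64) << np.uint64(
            2 * (k - 1 - j)
        )
    return packed


def _packed_mismatches(windows: np.ndarray, probes: np.ndarray) -> np.ndarray:
    """Hamming distances between packed windows and packed probes.

    XOR leaves 1-2 set bits per mismatched base; folding the odd bit onto
    the even bit and popcounting yields the mismatch count.
    """
    x = probes[:, None] ^ windows[None, :]
    y = (x | (x >> np.uint64(1))) & _ODD_BITS
    return np.bitwise_count(y)


def map_srnas(
    srna_sequences: Mapping[str, str] | Sequence[str],
    loci_sequences: Mapping[str, str] | Sequence[str],
    max_mismatch: int = 2,
) -> tuple[float, dict[str, int]]:
    """Map sRNAs onto locus sequences with bounded Hamming mismatches.

    An sRNA hits a locus if the sRNA or its reverse complement matches some
    substring of the locus with at most ``max_mismatch`` mismatched bases.
    Returns the fraction of loci with >= 1 hit and per-locus hit counts
    (number of distinct sRNAs hitting the locus).

    Probes of up to 32 nt over the ACGT alphabet use a 2-bit packed
    XOR/popcount scan; anything else falls back to an explicit window
    comparison.
    """
    if not isinstance(srna_sequences, Mapping):
        srna_sequences = {f"srna{i}": s for i, s in enumerate(srna_sequences)}
    if not isinstance(loci_sequences, Mapping):
        loci_sequences = {f"locus{i}": s for i, s in enumerate(loci_sequences)}
    if not loci_sequences:
        raise ValueError("no locus sequences supplied")
    # group forward/reverse probes by length; remember the owning sRNA index
    by_length: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    grouped: dict[int, list[tuple[int, np.ndarray]]] = {}
    for i, s in enumerate(srna_sequences.values()):
        s = s.upper()
        for probe in (s, reverse_complement(s)):
            grouped.setdefault(len(probe), []).append(
                (i, np.frombuffer(probe.encode(), dtype=np.uint8))
            )
    for k, entries in grouped.items():
        owners = np.array([i for i, _ in entries])
        matrix = np.stack([arr for _, arr in entries])
        probe_codes = _BASE_CODE[matrix]
        packed = None
        if k <= 32 and not (probe_codes == 255).any():
            packed = np.array(
                [_pack_kmers(row, k)[0] for row in probe_codes], dtype=np.uint64
            )
        by_length[k] = (owners, matrix, packed)

    n_srnas = len(srna_sequences)
    hit_counts: dict[str, int] = {}
    for name, locus_seq in loci_sequences.items():
        locus = np.frombuffer(locus_seq.upper().encode(), dtype=np.uint8)
        locus_codes = _BASE_CODE[locus]
        locus_clean = not (locus_codes == 255).any()
        hit_mask = np.zeros(n_srnas, dtype=bool)
        for k, (owners, matrix, packed) in by_length.items():
            if k > len(locus):
                continue
            if packed is not None and locus_clean:
                windows = _pack_kmers(locus_codes, k)
                mm = _packed_mismatches(windows, packed)
            else:
                views = np.lib.stride_tricks.sliding_window_view(locus, k)
                mm = (views[None, :, :] != matrix[:, None, :]).sum(axis=2)
            probe_hits = (mm <= max_mismatch).any(axis=1)
            hit_mask[owners[probe_hits]] = True
        hit_counts[name] = int(hit_mask.sum())
    fraction = sum(1 for v in hit_counts.values() if v > 0) / len(hit_counts)
    return fraction, hit_counts
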