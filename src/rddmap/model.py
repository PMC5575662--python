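"""Shared data types and coordinate conventions.

All coordinates are 0-based, half-open (`[start, end)`), on the forward
reference strand, for every module in the package.  GFF3's 1-based inclusive
convention is converted at the I/O boundary only (:mod:`rddmap.io`); BED is
native.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Strand",
    "Biotype",
    "GenomicInterval",
    "GeneModel",
    "AlignedRead",
    "PipelineConfig",
    "FeatureClass",
    "FeatureCountVector",
]


class Strand(str, Enum):
    """Strand of a genomic feature; ``UNSTRANDED`` is BED's '.'."""

    PLUS = "+"
    MINUS = "-"
    UNSTRANDED = "."

    def flipped(self) -> "Strand":
        if self is Strand.PLUS:
            return Strand.MINUS
        if self is Strand.MINUS:
            return Strand.PLUS
        return self


class Biotype(str, Enum):
    """The seven gene classes distinguished by the annotation."""

    PROTEIN_CODING = "protein_coding"
    TRANSPOSABLE_ELEMENT = "transposable_element"
    PSEUDOGENE = "pseudogene"
    NCRNA = "ncRNA"
    MIRNA = "miRNA"
    SNORNA = "snoRNA"
    TRNA = "tRNA"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: Strand = Strand.UNSTRANDED

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if not isinstance(self.strand, Strand):
            object.__setattr__(self, "strand", Strand(self.strand))

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """The midpoint base used for single-base feature assignment."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, delta: int) -> "GenomicInterval":
        return replace(self, start=self.start + delta, end=self.end + delta)


def _union_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total number of bases covered by a set of possibly-overlapping intervals."""
    total = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for spans in by_chrom.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


@dataclass
class GeneModel:
    """A gene collapsed to one exon/CDS structure (union over isoforms).

    ``body`` spans ``min(exon starts)..max(exon ends)``; bases of the body
    not covered by an exon are intronic.
    """

    gene_id: str
    biotype: Biotype
    body: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not isinstance(self.biotype, Biotype):
            self.biotype = Biotype(self.biotype)
        self.exons = sorted(self.exons, key=lambda iv: (iv.start, iv.end))
        self.cds = sorted(self.cds, key=lambda iv: (iv.start, iv.end))
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start < prev.end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise ValueError(f"{self.gene_id}: CDS {c} not contained in an exon")
        if self.exons:
            lo = min(e.start for e in self.exons)
            hi = max(e.end for e in self.exons)
            if self.body.start > lo or self.body.end < hi:
                raise ValueError(f"{self.gene_id}: body does not span exons")

    @property
    def strand(self) -> Strand:
        return self.body.strand

    @property
    def chrom(self) -> str:
        return self.body.chrom


@dataclass
class AlignedRead:
    """One genomic placement of a sequenced read.

    ``identity`` is the fraction of matching bases inside the aligned segment
    and ``aligned_fraction`` the fraction of the read that is aligned; both
    mirror the acceptance criteria applied to the RIP-seq alignments
    (>=80 % identity over >=70 % of the read, up to 20 placements).
    """

    read_id: str
    placement: GenomicInterval
    read_length: int
    identity: float
    aligned_fraction: float
    n_hits: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"{self.read_id}: identity {self.identity} outside [0,1]")
        if not (0.0 < self.aligned_fraction <= 1.0):
            raise ValueError(
                f"{self.read_id}: aligned_fraction {self.aligned_fraction} outside (0,1]"
            )
        if self.n_hits < 1:
            raise ValueError(f"{self.read_id}: n_hits must be >= 1")


@dataclass
class PipelineConfig:
    """All numeric thresholds of the analysis, with the study's defaults.

    min_read_len
        Reads shorter than this are dropped after trimming (30 nt, chosen to
        exclude the 24-nt siRNA fraction).
    min_identity / min_aligned_fraction / max_hits
        Alignment acceptance: >=80 % identity in >=70 % of the read, up to
        20 genomic placements (multi-mappers retained to keep repeat signal).
    flank
        Width of the gene flanking territory (2 kb each side).
    min_gene_reads
        Minimum reads on body + flanks for a gene to count as AGO4-associated.
    fc_threshold
        Linear mutant/wild-type fold change required in every mutant.
    locus_extension
        Extension applied to assembled lncRNA loci before overlap analysis.
    max_srna_mismatch
        Mismatches allowed when mapping AGO4-IP sRNAs onto loci.
    library_size_select
        cDNA size-selection window of the sequencing libraries (bp).
    """

    min_read_len: int = 30
    min_identity: float = 0.80
    min_aligned_fraction: float = 0.70
    max_hits: int = 20
    flank: int = 2000
    min_gene_reads: int = 50
    fc_threshold: float = 2.0
    locus_extension: int = 500
    max_srna_mismatch: int = 2
    library_size_select: tuple[int, int] = (200, 500)
    random_seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "min_read_len": self.min_read_len,
            "min_identity": self.min_identity,
            "min_aligned_fraction": self.min_aligned_fraction,
            "max_hits": self.max_hits,
            "flank": self.flank,
            "min_gene_reads": self.min_gene_reads,
            "locus_extension": self.locus_extension,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.fc_threshold < 1:
            raise ValueError(f"fc_threshold must be >= 1, got {self.fc_threshold}")
        if self.max_srna_mismatch < 0:
            raise ValueError("max_srna_mismatch must be >= 0")


class FeatureClass(str, Enum):
    """The six gene-centric territories plus the unassigned remainder."""

    UP2K = "up2k"
    UTR5 = "utr5"
    CDS = "cds"
    INTRON = "intron"
    UTR3 = "utr3"
    DOWN2K = "down2k"
    UNASSIGNED = "unassigned"


#: The six classes a read can be allocated to (order used in all tables).
ASSIGNED_CLASSES: tuple[FeatureClass, ...] = (
    FeatureClass.UP2K,
    FeatureClass.UTR5,
    FeatureClass.CDS,
    FeatureClass.INTRON,
    FeatureClass.UTR3,
    FeatureClass.DOWN2K,
)


@dataclass
class FeatureCountVector:
    """Per-gene read counts over the six assigned feature classes.

    ``counts`` counts placements (a read mapping to k <= 20 locations
    contributes once per placement); ``unique_reads`` counts distinct read
    identifiers, provided for reference.
    """

    gene_id: str
    counts: dict[FeatureClass, int] = field(default_factory=dict)
    unique_reads: int = 0

    def __post_init__(self) -> None:
        for cls in ASSIGNED_CLASSES:
            self.counts.setdefault(cls, 0)
        if any(v < 0 for v in self.counts.values()):
            raise ValueError(f"{self.gene_id}: negative feature count")

    @property
    def total(self) -> int:
        return sum(self.counts[c] for c in ASSIGNED_CLASSES)


def intervals_union_length(intervals: Sequence[GenomicInterval]) -> int:
    """Public wrapper for union length (used by simulators and tests)."""
    if not intervals:
        return 0
    return _union_length(intervals)


def check_within_genome(
    intervals: Iterable[GenomicInterval], lengths: Mapping[str, int]
) -> None:
    """Raise if any interval leaves its chromosome or names an unknown one."""
    for iv in intervals:
        if iv.chrom not in lengths:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > lengths[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {lengths[iv.chrom]}"
            )
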