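"""Once-only allocation of reads to gene features and genomic categories.

Every nuclear base is assigned to at most one ``(gene, feature)`` territory;
a read is then allocated by the label of its midpoint base, so each read is
counted exactly once.  Territory rules:

* gene bodies take precedence over any overlapping flank of a neighbour, so
  a read inside gene A that also lies within 2 kb of gene B stays with A;
* the intergenic gap between two consecutive gene bodies is divided at its
  midpoint: bases left of the midpoint belong to the upstream-side gene's
  flank, bases from the midpoint on to the downstream-side gene's flank,
  with each flank capped at the configured width (2 kb);
* flank classes are oriented by the owning gene's strand (the 5' flank of a
  minus-strand gene lies at higher coordinates);
* inside a gene body, CDS beats UTR beats intron when isoform structures
  disagree.

This is the testable core of the "each read is accounted only once"
allocation applied to the AGO4 RIP-seq libraries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._intervals import MergedIntervals, subtract_span
from .model import (
    ASSIGNED_CLASSES,
    AlignedRead,
    Biotype,
    FeatureClass,
    FeatureCountVector,
    GeneModel,
    GenomicInterval,
    Strand,
)

__all__ = [
    "FeatureIndex",
    "build_feature_index",
    "allocate_reads",
    "CategoryDistribution",
    "genomic_category_distribution",
    "feature_distribution",
    "heatmap_matrix",
]

Span = tuple[int, int]


@dataclass
class FeatureIndex:
    """Disjoint, sorted ``(start, end, gene, feature)`` territories per chromosome."""

    starts: dict[str, np.ndarray] = field(default_factory=dict)
    ends: dict[str, np.ndarray] = field(default_factory=dict)
    labels: dict[str, list[tuple[str, FeatureClass]]] = field(default_factory=dict)

    def lookup(self, chrom: str, pos: int) -> tuple[str, FeatureClass] | None:
        """Label of a single base, or None if unassigned."""
        starts = self.starts.get(chrom)
        if starts is None:
            return None
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < self.ends[chrom][i]:
            return self.labels[chrom][i]
        return None

    def territories(self) -> list[tuple[GenomicInterval, str, FeatureClass]]:
        out = []
        for chrom in sorted(self.starts):
            for s, e, lab in zip(
                self.starts[chrom], self.ends[chrom], self.labels[chrom]
            ):
                out.append((GenomicInterval(chrom, int(s), int(e)), lab[0], lab[1]))
        return out


def _gene_internal_segments(gene: GeneModel) -> list[tuple[Span, FeatureClass]]:
    """Partition a gene body into CDS/UTR5/UTR3/INTRON spans.

    Priority CDS > UTR > intron.  For genes without CDS every exonic base is
    treated as 5' UTR (entirely untranslated sequence).
    """
    body = (gene.body.start, gene.body.end)
    exon_spans = [(e.start, e.end) for e in gene.exons]
    cds_spans = [(c.start, c.end) for c in gene.cds]
    minus = gene.strand is Strand.MINUS
    segs: list[tuple[Span, FeatureClass]] = []

    for span in subtract_span(body, exon_spans):
        segs.append((span, FeatureClass.INTRON))
    if not cds_spans:
        for span in exon_spans:
            segs.append((span, FeatureClass.UTR5))
        segs.sort()
        return segs

    cds_lo = cds_spans[0][0]
    cds_hi = cds_spans[-1][1]
    for span in cds_spans:
        segs.append((span, FeatureClass.CDS))
    left_class = FeatureClass.UTR3 if minus else FeatureClass.UTR5
    right_class = FeatureClass.UTR5 if minus else FeatureClass.UTR3
    for exon in exon_spans:
        for s, e in subtract_span(exon, cds_spans):
            if e <= cds_lo:
                segs.append(((s, e), left_class))
            elif s >= cds_hi:
                segs.append(((s, e), right_class))
            else:
                # exonic, non-CDS, strictly between the CDS bounds (malformed
                # isoform union): attribute to the UTR of the nearer CDS edge,
                # ties to the gene's 5' side.
                to_left = s - cds_lo
                to_right = cds_hi - e
                if to_left < to_right or (to_left == to_right and not minus):
                    segs.append(((s, e), left_class))
                else:
                    segs.append(((s, e), right_class))
    segs.sort()
    return segs


def build_feature_index(
    annotation: Sequence[GeneModel],
    flank: int = 2000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> FeatureIndex:
    """Label genome territories with at most one ``(gene, feature)`` each.

    ``chrom_lengths`` clips the outermost flanks at chromosome ends; when it
    is not supplied the terminal flank simply extends ``flank`` bases past
    the last gene.
    """
    index = FeatureIndex()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)

    for chrom, genes in by_chrom.items():
        # 1. resolve body ownership: longer gene claims shared bases,
        #    ties broken by smaller start coordinate.
        order = sorted(genes, key=lambda g: (-len(g.body), g.body.start, g.gene_id))
        claimed: list[tuple[int, int, str]] = []  # disjoint, sorted
        owned: dict[str, list[Span]] = {}
        for g in order:
            blockers = [(s, e) for s, e, _ in claimed]
            pieces = subtract_span((g.body.start, g.body.end), blockers)
            owned[g.gene_id] = pieces
            for s, e in pieces:
                claimed.append((s, e, g.gene_id))
            claimed.sort()

        gene_by_id = {g.gene_id: g for g in genes}
        segments: list[tuple[int, int, str, FeatureClass]] = []

        # 2. intersect internal gene structure with owned body pieces
        for g in genes:
            internal = _gene_internal_segments(g)
            for (ps, pe) in owned[g.gene_id]:
                for (ss, se), cls in internal:
                    s, e = max(ss, ps), min(se, pe)
                    if s < e:
                        segments.append((s, e, g.gene_id, cls))

        # 3. merge owned pieces into blocks; note the gene at each edge
        blocks: list[tuple[int, int, str, str]] = []  # start, end, left owner, right owner
        for s, e, gid in claimed:
            if blocks and s <= blocks[-1][1]:
                bs, be, lo, _ = blocks[-1]
                blocks[-1] = (bs, max(be, e), lo, gid)
            else:
                blocks.append((s, e, gid, gid))

        # 4. flanks in the gaps between blocks, split at the gap midpoint
        def right_side_flank(gid: str) -> FeatureClass:
            g = gene_by_id[gid]
            return FeatureClass.UP2K if g.strand is Strand.MINUS else FeatureClass.DOWN2K

        def left_side_flank(gid: str) -> FeatureClass:
            g = gene_by_id[gid]
            return FeatureClass.DOWN2K if g.strand is Strand.MINUS else FeatureClass.UP2K

        if blocks:
            first = blocks[0]
            s = max(0, first[0] - flank)
            if s < first[0]:
                segments.append((s, first[0], first[2], left_side_flank(first[2])))
            for left, right in zip(blocks, blocks[1:]):
                a, b = left[1], right[0]
                if a >= b:
                    continue
                split = a + (b - a) // 2
                le = min(a + flank, split)
                if a < le:
                    segments.append((a, le, left[3], right_side_flank(left[3])))
                rs = max(split, b - flank)
                if rs < b:
                    segments.append((rs, b, right[2], left_side_flank(right[2])))
            last = blocks[-1]
            e = last[1] + flank
            if chrom_lengths is not None and chrom in chrom_lengths:
                e = min(e, chrom_lengths[chrom])
            if last[1] < e:
                segments.append((last[1], e, last[3], right_side_flank(last[3])))

        segments.sort()
        for (s1, e1, *_), (s2, _e2, *_) in zip(segments, segments[1:]):
            if s2 < e1:
                raise AssertionError(
                    f"internal error: overlapping territories on {chrom}"
                )
        index.starts[chrom] = np.asarray([s for s, *_ in segments], dtype=np.int64)
        index.ends[chrom] = np.asarray([e for _, e, *_ in segments], dtype=np.int64)
        index.labels[chrom] = [(gid, cls) for _, _, gid, cls in segments]
    return index


def allocate_reads(
    reads: Sequence[AlignedRead], index: FeatureIndex
) -> tuple[list[FeatureCountVector], int]:
    """Allocate each read once, by its midpoint base.

    Returns per-gene count vectors (placements per feature class, plus a
    distinct read-id count) and the number of unassigned reads.  The grand
    total over genes plus the unassigned count always equals the input size.
    """
    counts: dict[str, FeatureCountVector] = {}
    unique: dict[str, set[str]] = {}
    unassigned = 0
    unknown_chroms: set[str] = set()
    for r in reads:
        chrom = r.placement.chrom
        if chrom not in index.starts:
            unknown_chroms.add(chrom)
            unassigned += 1
            continue
        hit = index.lookup(chrom, r.placement.midpoint)
        if hit is None:
            unassigned += 1
            continue
        gid, cls = hit
        vec = counts.get(gid)
        if vec is None:
            vec = counts[gid] = FeatureCountVector(gene_id=gid)
            unique[gid] = set()
        vec.counts[cls] += 1
        unique[gid].add(r.read_id)
    if unknown_chroms:
        warnings.warn(
            f"reads on unknown chromosomes counted unassigned: {sorted(unknown_chroms)}"
        )
    for gid, vec in counts.items():
        vec.unique_reads = len(unique[gid])
    return sorted(counts.values(), key=lambda v: v.gene_id), unassigned


@dataclass
class CategoryDistribution:
    """Genome-level read origin: gene categories plus repeat association.

    ``fractions`` (protein_coding / transposon / other_genic / intergenic)
    sum to 1; ``repeat_associated`` is computed independently because a read
    can be both genic and repeat-derived.
    """

    fractions: dict[str, float]
    repeat_associated: float
    n_reads: int


def genomic_category_distribution(
    reads: Sequence[AlignedRead],
    annotation: Sequence[GeneModel],
    repeats: Sequence[GenomicInterval] = (),
    transposons: Sequence[GenomicInterval] = (),
) -> CategoryDistribution:
    """Assign each read one genomic category by its midpoint base.

    Priority when territories overlap: protein-coding gene body, then
    transposon, then any other annotated gene body, then intergenic.  The
    transposon territory is the union of TE-biotype gene bodies and any
    extra ``transposons`` intervals (e.g. a genome-wide TE coordinate set).
    """
    if not reads:
        raise ValueError("cannot compute a category distribution from zero reads")
    pc = MergedIntervals(
        g.body for g in annotation if g.biotype is Biotype.PROTEIN_CODING
    )
    te = MergedIntervals(
        [g.body for g in annotation if g.biotype is Biotype.TRANSPOSABLE_ELEMENT]
        + list(transposons)
    )
    other = MergedIntervals(
        g.body
        for g in annotation
        if g.biotype not in (Biotype.PROTEIN_CODING, Biotype.TRANSPOSABLE_ELEMENT)
    )
    rep = MergedIntervals(repeats)
    tallies = {"protein_coding": 0, "transposon": 0, "other_genic": 0, "intergenic": 0}
    n_repeat = 0
    for r in reads:
        chrom, mid = r.placement.chrom, r.placement.midpoint
        if pc.contains(chrom, mid):
            tallies["protein_coding"] += 1
        elif te.contains(chrom, mid):
            tallies["transposon"] += 1
        elif other.contains(chrom, mid):
            tallies["other_genic"] += 1
        else:
            tallies["intergenic"] += 1
        if rep.contains(chrom, mid):
            n_repeat += 1
    n = len(reads)
    return CategoryDistribution(
        fractions={k: v / n for k, v in tallies.items()},
        repeat_associated=n_repeat / n,
        n_reads=n,
    )


def feature_distribution(
    vectors: Sequence[FeatureCountVector],
) -> dict[FeatureClass, float]:
    """Percentage of allocated reads per feature class, over all genes."""
    totals = {cls: 0 for cls in ASSIGNED_CLASSES}
    for v in vectors:
        for cls in ASSIGNED_CLASSES:
            totals[cls] += v.counts[cls]
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("feature distribution undefined: zero allocated reads")
    return {cls: 100.0 * totals[cls] / grand for cls in ASSIGNED_CLASSES}


def heatmap_matrix(
    vectors: Sequence[FeatureCountVector], min_total: int = 0
) -> pd.DataFrame:
    """Gene x feature matrix: log10(count+1), row-normalized to the row max.

    Rows are genes with ``total >= min_total``; all-zero rows are dropped.
    Values lie in [0, 1]; suitable for direct heatmap plotting.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    rows = {
        v.gene_id: [math.log10(v.counts[c] + 1) for c in ASSIGNED_CLASSES]
        for v in vectors
        if v.total >= min_total and v.total > 0
    }
    if not rows:
        warnings.warn("heatmap_matrix: no genes pass the read threshold")
        return pd.DataFrame(columns=[c.value for c in ASSIGNED_CLASSES])
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[c.value for c in ASSIGNED_CLASSES]
    )
    return df.div(df.max(axis=1), axis=0)
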