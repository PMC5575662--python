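"""Readers and writers for the standard formats the pipeline consumes.

FASTA is handled through Biopython, GFF3 through gffutils, SAM through pysam,
and the tabular formats (BED, per-gene count tables, expression tables,
alignment-record TSV) through pandas.  GFF3's 1-based inclusive coordinates
are converted to the package-wide 0-based half-open convention here and only
here.
"""

from __future__ import annotations

import os
import warnings
from typing import Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AlignedRead,
    ASSIGNED_CLASSES,
    Biotype,
    FeatureCountVector,
    GeneModel,
    GenomicInterval,
    Strand,
)

__all__ = [
    "GFFParseError",
    "GFFStructureError",
    "BEDParseError",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "write_annotation",
    "read_intervals",
    "write_intervals",
    "read_reads_tsv",
    "write_reads_tsv",
    "read_reads_sam",
    "read_expression",
    "write_expression",
    "write_count_table",
    "read_count_table",
]


class GFFParseError(ValueError):
    """A GFF3 record that cannot be parsed; message names the file line."""


class GFFStructureError(ValueError):
    """A structurally invalid GFF3 hierarchy (orphan child, exon outside gene)."""


class BEDParseError(ValueError):
    """A BED record with invalid coordinates; message names the file line."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into ``{name: uppercase sequence}`` preserving order."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(
    sequences: Mapping[str, str], path: str | os.PathLike, width: int = 70
) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3

_TYPE_TO_BIOTYPE = {
    "gene": Biotype.PROTEIN_CODING,
    "protein_coding_gene": Biotype.PROTEIN_CODING,
    "transposable_element_gene": Biotype.TRANSPOSABLE_ELEMENT,
    "transposable_element": Biotype.TRANSPOSABLE_ELEMENT,
    "pseudogene": Biotype.PSEUDOGENE,
    "ncRNA_gene": Biotype.NCRNA,
    "miRNA_gene": Biotype.MIRNA,
    "snoRNA_gene": Biotype.SNORNA,
    "tRNA_gene": Biotype.TRNA,
}

_GENE_TYPES = set(_TYPE_TO_BIOTYPE)
_TRANSCRIPT_TYPES = {"mRNA", "transcript", "ncRNA", "miRNA", "snoRNA", "tRNA"}


def _prevalidate_gff3(path: str) -> None:
    """Cheap syntactic pass so parse errors can name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFFParseError(
                    f"line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GFFParseError(
                    f"line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise GFFParseError(
                    f"line {lineno}: invalid GFF3 coordinates {start}..{end}"
                )


def _interval_from_feature(feat: gffutils.Feature) -> GenomicInterval:
    # GFF3 is 1-based inclusive; internal convention 0-based half-open.
    strand = Strand(feat.strand) if feat.strand in ("+", "-") else Strand.UNSTRANDED
    return GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)


def read_annotation(path: str | os.PathLike) -> list[GeneModel]:
    """Parse a GFF3 annotation into one :class:`GeneModel` per gene.

    Both two-level (gene -> exon/CDS) and three-level (gene -> mRNA ->
    exon/CDS) hierarchies are accepted; multiple isoforms are collapsed to
    the exon/CDS union.  Unknown top-level feature types map to the ncRNA
    biotype with a warning.
    """
    path = str(path)
    _prevalidate_gff3(path)
    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    all_ids = {f.id for f in db.all_features()}
    genes: list[GeneModel] = []
    seen_gene_ids: set[str] = set()

    def _resolve_biotype(feat: gffutils.Feature) -> Biotype:
        attr = feat.attributes.get("biotype") or feat.attributes.get("gene_biotype")
        if attr:
            try:
                return Biotype(attr[0])
            except ValueError:
                pass
        if feat.featuretype in _TYPE_TO_BIOTYPE:
            return _TYPE_TO_BIOTYPE[feat.featuretype]
        warnings.warn(
            f"unknown gene feature type {feat.featuretype!r}; treating as ncRNA"
        )
        return Biotype.NCRNA

    # orphan detection: every exon/CDS must reach a known feature
    for feat in db.all_features():
        if feat.featuretype in ("exon", "CDS"):
            parents = feat.attributes.get("Parent", [])
            if not parents:
                raise GFFStructureError(
                    f"{feat.featuretype} {feat.id} has no Parent attribute"
                )
            for pid in parents:
                if pid not in all_ids:
                    raise GFFStructureError(
                        f"{feat.featuretype} {feat.id} references missing "
                        f"parent {pid!r}"
                    )

    for gene in db.all_features():
        if gene.featuretype in ("exon", "CDS") or gene.featuretype in _TRANSCRIPT_TYPES:
            continue
        if gene.attributes.get("Parent"):
            continue  # nested feature of another gene
        if gene.id in seen_gene_ids:
            raise GFFStructureError(f"duplicate gene id {gene.id!r}")
        seen_gene_ids.add(gene.id)
        body = _interval_from_feature(gene)
        exon_spans: set[tuple[int, int]] = set()
        cds_spans: set[tuple[int, int]] = set()
        for child in db.children(gene.id):
            iv = _interval_from_feature(child)
            if iv.chrom != body.chrom:
                raise GFFStructureError(
                    f"{gene.id}: child {child.id} on different chromosome"
                )
            if child.featuretype == "exon":
                if iv.start < body.start or iv.end > body.end:
                    raise GFFStructureError(
                        f"{gene.id}: exon {iv.start}-{iv.end} outside gene span "
                        f"{body.start}-{body.end}"
                    )
                exon_spans.add((iv.start, iv.end))
            elif child.featuretype == "CDS":
                cds_spans.add((iv.start, iv.end))
        exons = _merge_spans(exon_spans, body)
        cds = _merge_spans(cds_spans, body)
        if not exons:
            exons = [GenomicInterval(body.chrom, body.start, body.end, body.strand)]
        try:
            genes.append(
                GeneModel(
                    gene_id=gene.id,
                    biotype=_resolve_biotype(gene),
                    body=body,
                    exons=exons,
                    cds=cds,
                )
            )
        except ValueError as exc:
            raise GFFStructureError(str(exc)) from exc
    return genes


def _merge_spans(
    spans: set[tuple[int, int]], body: GenomicInterval
) -> list[GenomicInterval]:
    """Union of isoform spans as sorted non-overlapping intervals."""
    merged: list[GenomicInterval] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1].end:
            last = merged.pop()
            merged.append(
                GenomicInterval(body.chrom, last.start, max(last.end, e), body.strand)
            )
        else:
            merged.append(GenomicInterval(body.chrom, s, e, body.strand))
    return merged


def write_annotation(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as two-level GFF3 (gene with exon/CDS children)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            strand = g.body.strand.value if g.body.strand != Strand.UNSTRANDED else "."
            fh.write(
                f"{g.chrom}\trddmap\tgene\t{g.body.start + 1}\t{g.body.end}\t.\t"
                f"{strand}\t.\tID={g.gene_id};biotype={g.biotype.value}\n"
            )
            for exon in g.exons:
                fh.write(
                    f"{g.chrom}\trddmap\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{strand}\t.\tParent={g.gene_id}\n"
                )
            for c in g.cds:
                fh.write(
                    f"{g.chrom}\trddmap\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                    f"{strand}\t0\tParent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# BED


def read_intervals(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED3+ into intervals (kept in BED's native 0-based half-open)."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype={0: str}
        )
    except pd.errors.EmptyDataError:
        return []
    data_lines = _data_line_numbers(path)
    intervals: list[GenomicInterval] = []
    for i, row in enumerate(df.itertuples(index=False)):
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        if start < 0 or start >= end:
            lineno = data_lines[i] if i < len(data_lines) else i + 1
            raise BEDParseError(
                f"line {lineno}: invalid BED interval {chrom}:{start}-{end}"
            )
        strand = Strand.UNSTRANDED
        if len(row) >= 6 and str(row[5]) in ("+", "-"):
            strand = Strand(str(row[5]))
        intervals.append(GenomicInterval(chrom, start, end, strand))
    return intervals


def _data_line_numbers(path: str | os.PathLike) -> list[int]:
    numbers = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() and not line.startswith("#"):
                numbers.append(lineno)
    return numbers


def write_intervals(
    intervals: Sequence[GenomicInterval],
    path: str | os.PathLike,
    names: Sequence[str] | None = None,
    scores: Sequence[int | float] | None = None,
) -> None:
    """Write BED3 (or BED6 when names/scores/strands are informative)."""
    rows = []
    bed6 = names is not None or scores is not None or any(
        iv.strand != Strand.UNSTRANDED for iv in intervals
    )
    for i, iv in enumerate(intervals):
        if bed6:
            name = names[i] if names is not None else f"iv{i}"
            score = scores[i] if scores is not None else 0
            rows.append(
                (iv.chrom, iv.start, iv.end, name, score, iv.strand.value)
            )
        else:
            rows.append((iv.chrom, iv.start, iv.end))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Aligned reads (BED6+4 TSV, or SAM)

_READ_COLUMNS = [
    "chrom",
    "start",
    "end",
    "read_id",
    "score",
    "strand",
    "read_length",
    "identity",
    "aligned_fraction",
    "n_hits",
]


def write_reads_tsv(reads: Sequence[AlignedRead], path: str | os.PathLike) -> None:
    rows = [
        (
            r.placement.chrom,
            r.placement.start,
            r.placement.end,
            r.read_id,
            0,
            r.placement.strand.value,
            r.read_length,
            round(r.identity, 6),
            round(r.aligned_fraction, 6),
            r.n_hits,
        )
        for r in reads
    ]
    pd.DataFrame(rows, columns=_READ_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_reads_tsv(path: str | os.PathLike) -> list[AlignedRead]:
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=_READ_COLUMNS, dtype={"chrom": str}
        )
    except pd.errors.EmptyDataError:
        return []
    return [
        AlignedRead(
            read_id=str(row.read_id),
            placement=GenomicInterval(
                str(row.chrom), int(row.start), int(row.end), Strand(str(row.strand))
            ),
            read_length=int(row.read_length),
            identity=float(row.identity),
            aligned_fraction=float(row.aligned_fraction),
            n_hits=int(row.n_hits),
        )
        for row in df.itertuples(index=False)
    ]


def read_reads_sam(path: str | os.PathLike) -> list[AlignedRead]:
    """Read aligned records from SAM.

    Identity is derived from the NM tag over the aligned length, the aligned
    fraction from CIGAR, and the hit count from the NH tag (1 if absent).
    """
    import pysam

    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            aligned_len = aln.query_alignment_length
            read_len = aln.query_length or aligned_len
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            nh = aln.get_tag("NH") if aln.has_tag("NH") else 1
            identity = 1.0 - (nm / aligned_len) if aligned_len else 0.0
            reads.append(
                AlignedRead(
                    read_id=aln.query_name,
                    placement=GenomicInterval(
                        aln.reference_name,
                        aln.reference_start,
                        aln.reference_end,
                        Strand.MINUS if aln.is_reverse else Strand.PLUS,
                    ),
                    read_length=read_len,
                    identity=max(0.0, identity),
                    aligned_fraction=aligned_len / read_len if read_len else 1.0,
                    n_hits=int(nh),
                )
            )
    return reads


# ---------------------------------------------------------------------------
# Tables


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Expression table: gene_id column + one linear fold-change column per mutant."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError("expression table must have a 'gene_id' column")
    df = df.set_index("gene_id")
    if (df <= 0).any().any():
        raise ValueError("fold changes must be strictly positive")
    return df


def write_expression(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=True, index_label="gene_id")


def write_count_table(
    vectors: Sequence[FeatureCountVector], path: str | os.PathLike
) -> None:
    rows = [
        {
            "gene_id": v.gene_id,
            **{c.value: v.counts[c] for c in ASSIGNED_CLASSES},
            "total": v.total,
            "unique_reads": v.unique_reads,
        }
        for v in vectors
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_count_table(path: str | os.PathLike) -> list[FeatureCountVector]:
    df = pd.read_csv(path, sep="\t")
    vectors = []
    for row in df.itertuples(index=False):
        counts = {c: int(getattr(row, c.value)) for c in ASSIGNED_CLASSES}
        vectors.append(
            FeatureCountVector(
                gene_id=str(row.gene_id),
                counts=counts,
                unique_reads=int(getattr(row, "unique_reads", 0)),
            )
        )
    return vectors
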