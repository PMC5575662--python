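"""Shared fixtures: small simulation specs and random toy annotations."""

from __future__ import annotations

import numpy as np
import pytest

from rddmap.model import (
    AlignedRead,
    Biotype,
    GeneModel,
    GenomicInterval,
    Strand,
)
from rddmap.simulate import SimulationSpec, generate_annotation, generate_genome


@pytest.fixture
def small_spec() -> SimulationSpec:
    """A compact but complete study: two nuclear chromosomes + organelles."""
    return SimulationSpec(
        chromosome_lengths={"Chr1": 120_000, "Chr2": 80_000},
        organelle_lengths={"ChrC": 15_000, "ChrM": 15_000},
        n_genes=12,
        n_te_genes=2,
        seed=11,
    )


@pytest.fixture
def small_world(small_spec):
    genome = generate_genome(small_spec)
    annotation = generate_annotation(genome, small_spec)
    return small_spec, genome, annotation


def make_gene(
    gene_id: str,
    chrom: str,
    start: int,
    end: int,
    strand: str = "+",
    exons: list[tuple[int, int]] | None = None,
    cds: list[tuple[int, int]] | None = None,
    biotype: Biotype = Biotype.PROTEIN_CODING,
) -> GeneModel:
    """Terse gene constructor for hand-built fixtures."""
    st = Strand(strand)
    exon_ivs = [
        GenomicInterval(chrom, s, e, st) for s, e in (exons or [(start, end)])
    ]
    cds_ivs = [GenomicInterval(chrom, s, e, st) for s, e in (cds or [])]
    return GeneModel(
        gene_id=gene_id,
        biotype=biotype,
        body=GenomicInterval(chrom, start, end, st),
        exons=exon_ivs,
        cds=cds_ivs,
    )


def make_read(
    chrom: str,
    start: int,
    end: int,
    read_id: str = "r",
    strand: str = "+",
    read_length: int | None = None,
    identity: float = 0.95,
    aligned_fraction: float = 0.9,
    n_hits: int = 1,
) -> AlignedRead:
    return AlignedRead(
        read_id=read_id,
        placement=GenomicInterval(chrom, start, end, Strand(strand)),
        read_length=read_length if read_length is not None else end - start,
        identity=identity,
        aligned_fraction=aligned_fraction,
        n_hits=n_hits,
    )


def random_toy_annotation(
    rng: np.random.Generator, chrom: str, chrom_len: int, max_genes: int = 20
) -> list[GeneModel]:
    """Random gene models with deliberately awkward geometry.

    Gaps between genes range from tight (flanks collide, midpoint rule
    engaged) to wide; strands are random; some genes lack CDS.
    """
    genes: list[GeneModel] = []
    cursor = int(rng.integers(0, 3000))
    i = 0
    n_target = int(rng.integers(2, max_genes + 1))
    while i < n_target:
        length = int(rng.integers(300, 4000))
        if cursor + length + 100 > chrom_len:
            break
        start = cursor
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(rng.integers(1, 4))
        # alternate exon/intron segments, each >= 30 bp
        n_seg = 2 * k - 1
        if length < n_seg * 30:
            k, n_seg = 1, 1
        seg = 30 + rng.multinomial(length - n_seg * 30, np.full(n_seg, 1 / n_seg))
        bounds = start + np.concatenate([[0], np.cumsum(seg)])
        exons = [(int(bounds[j]), int(bounds[j + 1])) for j in range(0, n_seg, 2)]
        cds = None
        if rng.random() < 0.7 and (exons[0][1] - exons[0][0]) > 60:
            # CDS strictly inside the first/last exon span
            clo = exons[0][0] + 20
            chi = exons[-1][1] - 20
            cds = []
            for es, ee in exons:
                s, e = max(es, clo), min(ee, chi)
                if s < e:
                    cds.append((s, e))
        genes.append(
            make_gene(f"{chrom}_g{i}", chrom, start, end, strand, exons, cds)
        )
        cursor = end + int(rng.integers(100, 9000))
        i += 1
    return genes
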