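"""Synthetic genomes, annotations, reads, expression tables, sRNAs and
bisulphite clones with the statistical structure the analysis assumes.

The generator emulates the study conditions end to end, at desk scale:

* a nuclear/organellar genome partition ("Chr1..n" plus ChrC/ChrM), so the
  library-purity accounting is exercised;
* reads drawn from a class mixture over gene flanks, gene bodies, other
  intergenic space, transposons and organelles — the default mixture mirrors
  the published library composition (~0.3 % organellar; intergenic-dominated
  nuclear reads with flank bias);
* planted RdDM-repressed/-activated genes with consistent >= 2-fold
  expression changes in two mutants over a log-normal background;
* bisulphite clones with per-context methylation probabilities and an
  explicit conversion failure rate.

Every generator is a pure function of ``(spec, seed)``: the same spec gives
byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from ._intervals import MergedIntervals, complement_intervals
from .methylation import Context, enumerate_contexts
from .model import (
    AlignedRead,
    Biotype,
    GeneModel,
    GenomicInterval,
    Strand,
    intervals_union_length,
)

__all__ = [
    "SimulationSpec",
    "SyntheticGenome",
    "SizingError",
    "generate_genome",
    "generate_annotation",
    "simulate_rip_reads",
    "simulate_expression_table",
    "simulate_bisulphite_clones",
    "simulate_srnas",
    "extract_sequences",
    "READ_CLASSES",
]

READ_CLASSES = (
    "gene_flank_5",
    "gene_flank_3",
    "gene_body",
    "intergenic_other",
    "transposon",
    "organelle",
)

#: Default class mixture, mirroring the published library composition:
#: 0.3 % organellar reads; of the nuclear reads roughly 3.9 % transposon,
#: 19.7 % gene body and the rest intergenic with a strong 5' flank bias.
_DEFAULT_MIX = {
    "gene_flank_5": 0.300,
    "gene_flank_3": 0.140,
    "gene_body": 0.190,
    "intergenic_other": 0.328,
    "transposon": 0.039,
    "organelle": 0.003,
}


class SizingError(ValueError):
    """Requested genes cannot be placed at the required spacing."""


@dataclass
class SimulationSpec:
    """All knobs of the synthetic study, with the emulated-study defaults."""

    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"Chr1": 300_000, "Chr2": 200_000}
    )
    include_organelles: bool = True
    organelle_lengths: dict[str, int] = field(
        default_factory=lambda: {"ChrC": 30_000, "ChrM": 40_000}
    )
    n_genes: int = 30
    n_te_genes: int = 4
    gene_length_range: tuple[int, int] = (1200, 3000)
    n_exons_range: tuple[int, int] = (2, 4)
    gene_min_spacing: int = 5000
    flank: int = 2000
    repeat_density: float = 0.15
    repeat_length_range: tuple[int, int] = (200, 2000)
    te_fraction_of_repeats: float = 0.5
    read_class_mix: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MIX))
    read_length_range: tuple[int, int] = (30, 100)
    short_read_fraction: float = 0.10
    fail_fraction: float = 0.10
    planted_repressed: dict[str, float] = field(default_factory=dict)
    planted_activated: dict[str, float] = field(default_factory=dict)
    fc_threshold: float = 2.0
    expression_noise_sd: float = 0.25
    clone_meth_prob: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.9, "CHG": 0.7, "CHH": 0.4}
    )
    mutant_clone_meth_prob: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.85, "CHG": 0.3, "CHH": 0.1}
    )
    n_clones: int = 16
    conversion_rate: float = 0.99
    n_srnas: int = 150
    srna_length: int = 24
    srna_max_planted_mismatch: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.read_class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"read_class_mix sums to {total}, expected 1")
        for name, p in self.read_class_mix.items():
            if name not in READ_CLASSES:
                raise ValueError(f"unknown read class {name!r}")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"read class probability {name}={p} outside [0,1]")
        for probs in (self.clone_meth_prob, self.mutant_clone_meth_prob):
            for ctx, p in probs.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"methylation probability {ctx}={p} outside [0,1]")
        if not (0.0 <= self.conversion_rate <= 1.0):
            raise ValueError("conversion_rate outside [0,1]")
        if set(self.planted_repressed) & set(self.planted_activated):
            raise ValueError("planted repressed/activated gene sets must be disjoint")

    def rng(self, stage: int) -> np.random.Generator:
        """A stage-specific generator, a pure function of (seed, stage)."""
        return np.random.default_rng([self.seed, stage])


class SyntheticGenome(NamedTuple):
    sequences: dict[str, str]
    repeats: list[GenomicInterval]
    transposons: list[GenomicInterval]
    nuclear_chromosomes: list[str]
    organelles: list[str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def nuclear_lengths(self) -> dict[str, int]:
        return {c: len(self.sequences[c]) for c in self.nuclear_chromosomes}


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# AT-rich composition typical of the emulated genome
_BASE_P = np.array([0.32, 0.18, 0.18, 0.32])


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(4, size=length, p=_BASE_P)
    return _BASES[idx].tobytes().decode()


def generate_genome(spec: SimulationSpec) -> SyntheticGenome:
    """Random genome with repeat and transposon interval sets.

    Repeat intervals are placed uniformly (allowed to overlap) until their
    union covers approximately ``repeat_density`` of each nuclear
    chromosome; a configurable fraction of them is additionally marked as
    transposons.
    """
    rng = spec.rng(1)
    sequences: dict[str, str] = {}
    nuclear = list(spec.chromosome_lengths)
    for chrom, length in spec.chromosome_lengths.items():
        sequences[chrom] = _random_sequence(rng, length)
    organelles: list[str] = []
    if spec.include_organelles:
        for chrom, length in spec.organelle_lengths.items():
            sequences[chrom] = _random_sequence(rng, length)
            organelles.append(chrom)

    repeats: list[GenomicInterval] = []
    transposons: list[GenomicInterval] = []
    lo, hi = spec.repeat_length_range
    for chrom in nuclear:
        clen = spec.chromosome_lengths[chrom]
        if spec.repeat_density <= 0:
            continue
        target = spec.repeat_density * clen
        chrom_repeats: list[GenomicInterval] = []
        while intervals_union_length(chrom_repeats) < target:
            rlen = int(rng.integers(lo, min(hi, clen) + 1))
            start = int(rng.integers(0, clen - rlen + 1))
            iv = GenomicInterval(chrom, start, start + rlen)
            chrom_repeats.append(iv)
            if rng.random() < spec.te_fraction_of_repeats:
                transposons.append(iv)
        repeats.extend(chrom_repeats)
    return SyntheticGenome(sequences, repeats, transposons, nuclear, organelles)


def _allocate_counts(total: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of ``total`` across weights."""
    w = np.asarray(weights, dtype=float)
    exact = total * w / w.sum()
    counts = np.floor(exact).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(exact - counts))
    for i in order[:remainder]:
        counts[i] += 1
    return counts.tolist()


def generate_annotation(
    genome: SyntheticGenome, spec: SimulationSpec
) -> list[GeneModel]:
    """Place multi-exon genes at >= ``gene_min_spacing`` separation.

    Gene counts per chromosome are proportional to chromosome length.  Each
    protein-coding gene has 2+ exons with CDS flanked by UTRs; transposable
    element genes (single-exon, no CDS) are placed inside transposon
    intervals that do not collide with other genes.
    """
    rng = spec.rng(2)
    lengths = genome.nuclear_lengths
    chroms = list(lengths)
    per_chrom = _allocate_counts(spec.n_genes, [lengths[c] for c in chroms])
    genes: list[GeneModel] = []
    glo, ghi = spec.gene_length_range
    spacing = spec.gene_min_spacing
    counter = 0
    for chrom, m in zip(chroms, per_chrom):
        if m == 0:
            continue
        clen = lengths[chrom]
        body_lengths = rng.integers(glo, ghi + 1, size=m)
        required = int(body_lengths.sum()) + (m + 1) * spacing
        if required > clen:
            raise SizingError(
                f"cannot place {m} genes of mean {body_lengths.mean():.0f} bp "
                f"on {chrom} ({clen} bp) at {spacing} bp spacing"
            )
        slack = clen - required
        extra = rng.multinomial(slack, np.full(m + 1, 1.0 / (m + 1)))
        cursor = 0
        for j in range(m):
            cursor += spacing + int(extra[j])
            counter += 1
            genes.append(
                _make_gene(
                    rng,
                    gene_id=f"g{counter:04d}",
                    chrom=chrom,
                    start=cursor,
                    length=int(body_lengths[j]),
                    n_exons_range=spec.n_exons_range,
                )
            )
            cursor += int(body_lengths[j])

    # transposable-element genes inside TE intervals, clear of other genes
    occupied = MergedIntervals([g.body for g in genes])
    te_candidates = [
        iv
        for iv in genome.transposons
        if len(iv) >= 300 and not occupied.overlaps_interval(iv.chrom, iv.start, iv.end)
    ]
    rng.shuffle(te_candidates)
    placed = 0
    for iv in te_candidates:
        if placed >= spec.n_te_genes:
            break
        placed += 1
        strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
        body = GenomicInterval(iv.chrom, iv.start, iv.end, strand)
        genes.append(
            GeneModel(
                gene_id=f"te{placed:03d}",
                biotype=Biotype.TRANSPOSABLE_ELEMENT,
                body=body,
                exons=[body],
                cds=[],
            )
        )
    if placed < spec.n_te_genes:
        warnings.warn(
            f"placed only {placed}/{spec.n_te_genes} TE genes inside TE intervals"
        )
    return genes


def _make_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    start: int,
    length: int,
    n_exons_range: tuple[int, int],
) -> GeneModel:
    strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
    k = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
    n_seg = 2 * k - 1  # exon, intron, ..., exon
    min_seg = 20
    if length < n_seg * min_seg:
        k, n_seg = 2, 3
    seg = min_seg + rng.multinomial(
        length - n_seg * min_seg, np.full(n_seg, 1.0 / n_seg)
    )
    bounds = start + np.concatenate([[0], np.cumsum(seg)])
    body = GenomicInterval(chrom, start, start + length, strand)
    exons = [
        GenomicInterval(chrom, int(bounds[i]), int(bounds[i + 1]), strand)
        for i in range(0, n_seg, 2)
    ]
    exonic_len = sum(len(e) for e in exons)
    u5 = int(exonic_len * rng.uniform(0.10, 0.30))
    u3 = int(exonic_len * rng.uniform(0.05, 0.20))
    if strand is Strand.MINUS:
        u5, u3 = u3, u5  # genomic-left end is the 3' end of a minus gene
    cds: list[GenomicInterval] = []
    walked = 0
    for e in exons:
        lo = max(e.start, e.start + (u5 - walked))
        hi = min(e.end, e.start + (exonic_len - u3 - walked))
        if lo < hi:
            cds.append(GenomicInterval(chrom, lo, hi, strand))
        walked += len(e)
    return GeneModel(
        gene_id=gene_id,
        biotype=Biotype.PROTEIN_CODING,
        body=body,
        exons=exons,
        cds=cds,
    )


def _class_territories(
    genome: SyntheticGenome, annotation: Sequence[GeneModel], spec: SimulationSpec
) -> dict[str, list[GenomicInterval]]:
    """Disjoint genomic territory per read class.

    Priority gene_body > gene_flank_5 > gene_flank_3 > transposon keeps the
    classes disjoint so the planted mixture is exactly recoverable by a
    point-in-territory recount.
    """
    lengths = genome.lengths
    coding = [g for g in annotation if g.biotype is not Biotype.TRANSPOSABLE_ELEMENT]
    bodies = [g.body for g in coding]
    flank5: list[GenomicInterval] = []
    flank3: list[GenomicInterval] = []
    for g in coding:
        clen = lengths[g.chrom]
        if g.strand is Strand.MINUS:
            up = (g.body.end, min(clen, g.body.end + spec.flank))
            down = (max(0, g.body.start - spec.flank), g.body.start)
        else:
            up = (max(0, g.body.start - spec.flank), g.body.start)
            down = (g.body.end, min(clen, g.body.end + spec.flank))
        if up[0] < up[1]:
            flank5.append(GenomicInterval(g.chrom, up[0], up[1]))
        if down[0] < down[1]:
            flank3.append(GenomicInterval(g.chrom, down[0], down[1]))

    def minus(intervals, blockers):
        blocked = MergedIntervals(blockers) if blockers else None
        if blocked is None:
            return list(intervals)
        out = []
        lengths_b = {}
        # subtract via complement over each interval span
        for iv in intervals:
            sub_blockers = [
                GenomicInterval(iv.chrom, max(int(s), iv.start), min(int(e), iv.end))
                for s, e in zip(
                    blocked.starts.get(iv.chrom, []), blocked.ends.get(iv.chrom, [])
                )
                if int(s) < iv.end and int(e) > iv.start
            ]
            if not sub_blockers:
                out.append(iv)
                continue
            covered = MergedIntervals(sub_blockers)
            cursor = iv.start
            for s, e in zip(covered.starts[iv.chrom], covered.ends[iv.chrom]):
                if int(s) > cursor:
                    out.append(GenomicInterval(iv.chrom, cursor, int(s)))
                cursor = max(cursor, int(e))
            if cursor < iv.end:
                out.append(GenomicInterval(iv.chrom, cursor, iv.end))
        return out

    te = minus(genome.transposons, bodies + flank5 + flank3)
    nuclear_blockers = bodies + flank5 + flank3 + list(genome.transposons)
    intergenic = complement_intervals(nuclear_blockers, genome.nuclear_lengths)
    organelle = [
        GenomicInterval(c, 0, lengths[c]) for c in genome.organelles
    ]
    return {
        "gene_body": bodies,
        "gene_flank_5": minus(flank5, bodies),
        "gene_flank_3": minus(flank3, bodies + flank5),
        "transposon": te,
        "intergenic_other": intergenic,
        "organelle": organelle,
    }


def simulate_rip_reads(
    genome: SyntheticGenome,
    annotation: Sequence[GeneModel],
    spec: SimulationSpec,
    n_reads: int,
) -> list[AlignedRead]:
    """Draw aligned reads from the class mixture.

    Each read first samples its class, then a midpoint uniform over that
    class's territory; identity / aligned fraction / hit count are sampled
    so that ``fail_fraction`` of reads fail the mapping acceptance filter,
    and ``short_read_fraction`` are shorter than 30 nt (removed by the
    length filter).  Reads are emitted as already-aligned records; the
    attributes are simulated, not recomputed from sequence.
    """
    rng = spec.rng(3)
    territories = _class_territories(genome, annotation, spec)
    active = [c for c in READ_CLASSES if spec.read_class_mix.get(c, 0.0) > 0]
    arrays = {}
    for cls in active:
        ivs = territories[cls]
        total = sum(len(iv) for iv in ivs)
        if total == 0:
            raise ValueError(
                f"read class {cls!r} has an empty territory "
                "(organelle class with organelles disabled?)"
            )
        cum = np.concatenate([[0], np.cumsum([len(iv) for iv in ivs])])
        arrays[cls] = (ivs, cum, total)

    probs = np.array([spec.read_class_mix[c] for c in active])
    probs = probs / probs.sum()
    class_draw = rng.choice(len(active), size=n_reads, p=probs)
    lengths = genome.lengths
    lo, hi = spec.read_length_range
    reads: list[AlignedRead] = []
    for i in range(n_reads):
        cls = active[class_draw[i]]
        ivs, cum, total = arrays[cls]
        offset = int(rng.integers(0, total))
        k = int(np.searchsorted(cum, offset, side="right")) - 1
        iv = ivs[k]
        mid = iv.start + (offset - int(cum[k]))
        if rng.random() < spec.short_read_fraction:
            rlen = int(rng.integers(20, 30))
        else:
            rlen = int(rng.integers(lo, hi + 1))
        clen = lengths[iv.chrom]
        start = max(0, min(mid - rlen // 2, clen - rlen))
        end = start + rlen
        strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
        if rng.random() < spec.fail_fraction:
            mode = int(rng.integers(0, 3))
            identity = rng.uniform(0.5, 0.79) if mode == 0 else rng.uniform(0.85, 1.0)
            af = rng.uniform(0.3, 0.69) if mode == 1 else rng.uniform(0.75, 1.0)
            n_hits = int(rng.integers(21, 41)) if mode == 2 else 1
        else:
            identity = rng.uniform(0.85, 1.0)
            af = rng.uniform(0.75, 1.0)
            if cls == "transposon":
                n_hits = int(rng.integers(1, 21))
            else:
                n_hits = 1 if rng.random() < 0.9 else int(rng.integers(2, 21))
        reads.append(
            AlignedRead(
                read_id=f"read{i:07d}",
                placement=GenomicInterval(iv.chrom, start, end, strand),
                read_length=rlen,
                identity=float(identity),
                aligned_fraction=float(af),
                n_hits=n_hits,
            )
        )
    return reads


def simulate_expression_table(
    annotation: Sequence[GeneModel],
    spec: SimulationSpec,
    mutants: Sequence[str] = ("nrpd1", "nrpe1"),
):
    """Mutant/wild-type linear fold changes with planted target genes.

    Planted repressed genes receive their planted fold change (times
    log-normal noise) in every mutant column; planted activated genes the
    reciprocal; background genes draw log2 fold changes from
    ``N(0, expression_noise_sd)``.
    """
    import pandas as pd

    rng = spec.rng(4)
    gene_ids = [g.gene_id for g in annotation]
    known = set(gene_ids)
    for planted in (spec.planted_repressed, spec.planted_activated):
        for gid, fc in planted.items():
            if gid not in known:
                raise ValueError(f"planted gene {gid!r} is not annotated")
            if fc < spec.fc_threshold:
                raise ValueError(
                    f"planted fold change {fc} for {gid!r} is below the "
                    f"detection threshold {spec.fc_threshold}"
                )
    sd = spec.expression_noise_sd
    data = {}
    for mutant in mutants:
        noise = rng.normal(0.0, sd, size=len(gene_ids)) if sd > 0 else np.zeros(
            len(gene_ids)
        )
        values = np.power(2.0, noise)
        for i, gid in enumerate(gene_ids):
            if gid in spec.planted_repressed:
                values[i] *= spec.planted_repressed[gid]
            elif gid in spec.planted_activated:
                values[i] /= spec.planted_activated[gid]
        data[mutant] = values
    return pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))


def simulate_bisulphite_clones(
    region_sequence: str,
    spec: SimulationSpec,
    meth_prob: Mapping[str, float] | None = None,
    strands: Sequence[Strand | str] = (Strand.PLUS,),
) -> list[tuple[str, str, Strand]]:
    """Bisulphite-converted clone sequences of one amplicon.

    Each clone is the region sequence in which every cytosine (of the
    clone's strand) is independently kept with the context's methylation
    probability, or otherwise converted (C->T on plus, G->A on minus in
    reference orientation) with probability ``conversion_rate``.  Sites with
    UNDEFINED context (sequence ends, Ns) follow the CHH probability unless
    an explicit ``undefined`` key is supplied.  Returns
    ``(clone_id, sequence, strand)`` triples, sequences in reference
    orientation.
    """
    rng = spec.rng(5)
    probs = dict(spec.clone_meth_prob if meth_prob is None else meth_prob)
    seq = region_sequence.upper()
    sites = enumerate_contexts(seq)
    if not sites:
        warnings.warn("region contains no cytosines; clones returned unchanged")
    clones: list[tuple[str, str, Strand]] = []
    for strand in (Strand(s) for s in strands):
        strand_sites = [s for s in sites if s.strand is strand]
        for c in range(spec.n_clones):
            bases = list(seq)
            for site in strand_sites:
                if site.context is Context.UNDEFINED:
                    p = probs.get("undefined", probs.get("CHH", 0.0))
                else:
                    p = probs.get(site.context.value, 0.0)
                if rng.random() < p:
                    continue  # methylated: protected from conversion
                if rng.random() < spec.conversion_rate:
                    bases[site.position] = "T" if strand is Strand.PLUS else "A"
            clones.append(
                (f"clone_{strand.value}_{c:02d}", "".join(bases), strand)
            )
    return clones


def extract_sequences(
    sequences: Mapping[str, str], intervals: Sequence[GenomicInterval]
) -> dict[str, str]:
    """Substring of the genome for each interval, keyed ``chrom:start-end``."""
    return {
        f"{iv.chrom}:{iv.start}-{iv.end}": sequences[iv.chrom][iv.start : iv.end]
        for iv in intervals
    }


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def simulate_srnas(
    sequences: Mapping[str, str],
    source_intervals: Sequence[GenomicInterval],
    spec: SimulationSpec,
) -> dict[str, str]:
    """Small RNAs sampled from source intervals, with planted mismatches.

    Each sRNA is a ``srna_length``-mer drawn from a random position inside a
    source interval (chosen proportional to length), mutated at up to
    ``srna_max_planted_mismatch`` positions, and reverse-complemented with
    probability 1/2 — emulating an AGO4-bound sRNA population that maps back
    to the loci within the mismatch allowance.
    """
    rng = spec.rng(6)
    k = spec.srna_length
    eligible = [iv for iv in source_intervals if len(iv) >= k]
    if not eligible:
        raise ValueError(f"no source interval is >= {k} bp")
    weights = np.array([len(iv) - k + 1 for iv in eligible], dtype=float)
    weights /= weights.sum()
    srnas: dict[str, str] = {}
    bases = "ACGT"
    for i in range(spec.n_srnas):
        iv = eligible[int(rng.choice(len(eligible), p=weights))]
        pos = int(rng.integers(iv.start, iv.end - k + 1))
        s = list(sequences[iv.chrom][pos : pos + k])
        n_mut = int(rng.integers(0, spec.srna_max_planted_mismatch + 1))
        for j in rng.choice(k, size=n_mut, replace=False):
            current = s[j]
            s[j] = rng.choice([b for b in bases if b != current])
        seq = "".join(s)
        if rng.random() < 0.5:
            seq = seq.translate(_COMPLEMENT)[::-1]
        srnas[f"srna{i:04d}"] = seq
    return srnas
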