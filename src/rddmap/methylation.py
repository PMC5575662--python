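"""Bisulphite clone analysis: context enumeration, per-site methylation
levels and genotype comparison.

Cytosine contexts follow the plant convention: CG, CHG and CHH, where H is
A, C or T.  On the plus strand a cytosine is classified by its two
downstream reference bases; on the minus strand every reference G is a
cytosine whose downstream bases are the upstream reference bases,
complemented.  Clones are assumed to be ungapped full-length copies of the
amplicon (the usual situation for short PCR products cloned after
conversion); at each site a retained C is read as methylated and a
converted T as unmethylated, any other base is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .model import Strand

__all__ = [
    "Context",
    "CytosineSite",
    "GenotypeComparison",
    "enumerate_contexts",
    "clone_methylation_levels",
    "conversion_efficiency",
    "compare_genotypes",
]

_H = set("ACT")
_H_COMP = set("AGT")  # complements of H, as seen on the plus strand


class Context(str, Enum):
    CG = "CG"
    CHG = "CHG"
    CHH = "CHH"
    UNDEFINED = "undefined"


@dataclass
class CytosineSite:
    """One cytosine position on the reference, with clone counts."""

    position: int
    strand: Strand
    context: Context
    methylated_clones: int = 0
    total_clones: int = 0

    @property
    def level(self) -> float | None:
        """Methylated fraction across scored clones (None if unscored)."""
        if self.total_clones == 0:
            return None
        return self.methylated_clones / self.total_clones


def enumerate_contexts(reference_sequence: str) -> list[CytosineSite]:
    """All cytosine sites on both strands of a reference region.

    Sites too close to the sequence end to have two downstream bases, or
    with an N among the classifying bases, get the UNDEFINED context.
    Sorted by (position, strand).
    """
    seq = reference_sequence.upper()
    n = len(seq)
    sites: list[CytosineSite] = []
    for i, base in enumerate(seq):
        if base == "C":
            ctx = _plus_context(seq, i, n)
            sites.append(CytosineSite(i, Strand.PLUS, ctx))
        elif base == "G":
            ctx = _minus_context(seq, i)
            sites.append(CytosineSite(i, Strand.MINUS, ctx))
    return sites


def _plus_context(seq: str, i: int, n: int) -> Context:
    if i + 1 >= n:
        return Context.UNDEFINED
    b1 = seq[i + 1]
    if b1 == "G":
        return Context.CG
    if b1 not in _H:
        return Context.UNDEFINED
    if i + 2 >= n:
        return Context.UNDEFINED
    b2 = seq[i + 2]
    if b2 == "G":
        return Context.CHG
    if b2 in _H:
        return Context.CHH
    return Context.UNDEFINED


def _minus_context(seq: str, i: int) -> Context:
    # downstream bases of a minus-strand C are at i-1, i-2, complemented
    if i - 1 < 0:
        return Context.UNDEFINED
    b1 = seq[i - 1]
    if b1 == "C":  # complement G
        return Context.CG
    if b1 not in _H_COMP:
        return Context.UNDEFINED
    if i - 2 < 0:
        return Context.UNDEFINED
    b2 = seq[i - 2]
    if b2 == "C":
        return Context.CHG
    if b2 in _H_COMP:
        return Context.CHH
    return Context.UNDEFINED


def clone_methylation_levels(
    sites: Sequence[CytosineSite],
    clone_sequences: Iterable[tuple[str, Strand] | tuple[str, str]],
    reference_length: int | None = None,
) -> list[CytosineSite]:
    """Fill clone counts for each site from aligned clone sequences.

    ``clone_sequences`` yields ``(sequence, strand)`` pairs; every sequence
    must be in reference (plus) orientation and the same length as the
    reference.  A plus-strand clone scores plus-strand sites: C means the
    cytosine was methylated (protected), T means it was converted.  A
    minus-strand clone scores minus-strand sites via the complementary
    logic: G retained = methylated, A = converted.  Any other base at the
    site is excluded from the clone total.
    """
    scored = [
        CytosineSite(s.position, s.strand, s.context) for s in sites
    ]
    clones = list(clone_sequences)
    for seq, strand in clones:
        strand = Strand(strand)
        if reference_length is not None and len(seq) != reference_length:
            raise ValueError(
                f"clone length {len(seq)} != reference length {reference_length}"
            )
        seq = seq.upper()
        for site in scored:
            if site.strand is not strand:
                continue
            if site.position >= len(seq):
                raise ValueError("clone shorter than site positions require")
            base = seq[site.position]
            if strand is Strand.PLUS:
                meth, conv = "C", "T"
            else:
                meth, conv = "G", "A"
            if base == meth:
                site.methylated_clones += 1
                site.total_clones += 1
            elif base == conv:
                site.total_clones += 1
            # other bases (SNP / sequencing error): excluded
    return scored


def conversion_efficiency(control_sites: Sequence[CytosineSite]) -> float:
    """Converted fraction of cytosine observations in an unmethylated control.

    The control is a region known to carry no methylation (the chloroplast
    *psaA* fragment in the original assay), so every retained C reflects a
    conversion failure.
    """
    total = sum(s.total_clones for s in control_sites)
    if total == 0:
        raise ValueError("conversion efficiency undefined: no cytosine observations")
    converted = sum(s.total_clones - s.methylated_clones for s in control_sites)
    return converted / total


@dataclass
class GenotypeComparison:
    """Per-site methylation differences between two genotypes.

    ``deltas`` are mutant minus wild-type levels (absolute difference in
    methylated fraction, i.e. percentage points / 100).  Counts are per
    context at the stated minimum absolute difference.
    """

    deltas: list[float | None]
    min_delta: float
    hypo: dict[Context, int] = field(default_factory=dict)
    hyper: dict[Context, int] = field(default_factory=dict)
    unchanged: dict[Context, int] = field(default_factory=dict)

    def counts(self, context: Context) -> tuple[int, int, int]:
        return (
            self.hypo.get(context, 0),
            self.hyper.get(context, 0),
            self.unchanged.get(context, 0),
        )


def compare_genotypes(
    sites_wt: Sequence[CytosineSite],
    sites_mut: Sequence[CytosineSite],
    min_delta: float = 0.1,
) -> GenotypeComparison:
    """Call hypo-/hyper-methylated sites between wild type and mutant.

    Both site lists must come from the same reference (same positions,
    strands and contexts).  A site is hypo-methylated when the mutant level
    is at least ``min_delta`` below wild type, hyper when at least
    ``min_delta`` above; sites unscored in either genotype are skipped.
    """
    if len(sites_wt) != len(sites_mut):
        raise ValueError("site lists differ in length")
    comparison = GenotypeComparison(deltas=[], min_delta=min_delta)
    for wt, mut in zip(sites_wt, sites_mut):
        if (wt.position, wt.strand, wt.context) != (
            mut.position,
            mut.strand,
            mut.context,
        ):
            raise ValueError(
                f"site mismatch at position {wt.position}: genotypes were "
                "scored on different references"
            )
        if wt.level is None or mut.level is None:
            comparison.deltas.append(None)
            continue
        delta = mut.level - wt.level
        comparison.deltas.append(delta)
        ctx = wt.context
        if delta <= -min_delta:
            comparison.hypo[ctx] = comparison.hypo.get(ctx, 0) + 1
        elif delta >= min_delta:
            comparison.hyper[ctx] = comparison.hyper.get(ctx, 0) + 1
        else:
            comparison.unchanged[ctx] = comparison.unchanged.get(ctx, 0) + 1
    return comparison
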