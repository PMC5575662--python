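"""RdDM target-gene classification.

Genes carrying enough AGO4-associated lncRNA reads (body + 2 kb flanks) are
candidate RdDM targets.  Intersecting them with mutant/wild-type expression
fold changes of RdDM polymerase mutants splits them into:

* RdDM-repressed genes — up-regulated at least ``fc_threshold``-fold in
  every mutant (silencing lost when the pathway is broken);
* RdDM-activated genes — down-regulated at least ``fc_threshold``-fold in
  every mutant (expression depends on an intact pathway).

Fold changes are linear-scale mutant/wild-type ratios taken as given (the
expression statistics of the upstream microarray/RNA-seq analysis are not
recomputed here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .model import ASSIGNED_CLASSES, FeatureClass, FeatureCountVector

__all__ = [
    "TargetSets",
    "candidate_genes",
    "classify_targets",
    "compare_feature_profiles",
    "venn_counts",
]

log = logging.getLogger(__name__)


@dataclass
class TargetSets:
    """Candidate genes and their repressed/activated classification."""

    candidates: set[str]
    repressed: set[str] = field(default_factory=set)
    activated: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.repressed & self.activated:
            raise ValueError("a gene cannot be both repressed and activated")
        if not (self.repressed <= self.candidates and self.activated <= self.candidates):
            raise ValueError("classified genes must be candidates")


def candidate_genes(
    vectors: Sequence[FeatureCountVector], min_gene_reads: int = 50
) -> set[str]:
    """Genes with at least ``min_gene_reads`` allocated reads (inclusive)."""
    return {v.gene_id for v in vectors if v.total >= min_gene_reads}


def classify_targets(
    candidates: set[str],
    expression: pd.DataFrame,
    fc_threshold: float = 2.0,
) -> TargetSets:
    """Split candidates by consistent fold change across all mutant columns.

    ``expression`` is indexed by gene id with one linear fold-change column
    per mutant.  Candidates missing from the table are dropped with a log
    notice (intersection semantics).  Repressed requires fold change >=
    ``fc_threshold`` in every column; activated requires <= 1/fc_threshold
    in every column.
    """
    if (expression <= 0).any().any():
        raise ValueError("fold changes must be strictly positive")
    present = candidates & set(expression.index.astype(str))
    missing = len(candidates) - len(present)
    if missing:
        log.info(
            "classify_targets: %d candidate genes absent from the expression "
            "table were dropped", missing,
        )
    sub = expression.loc[sorted(present)]
    repressed = set(sub.index[(sub >= fc_threshold).all(axis=1)])
    activated = set(sub.index[(sub <= 1.0 / fc_threshold).all(axis=1)])
    return TargetSets(candidates=present, repressed=repressed, activated=activated)


def compare_feature_profiles(
    vectors: Sequence[FeatureCountVector],
    set_a: set[str],
    set_b: set[str],
) -> pd.DataFrame:
    """Per-feature read percentages for two gene sets, plus their ratio.

    For each set the percentage is that set's reads in the feature class
    over the set's total reads.  Columns: ``pct_a``, ``pct_b``,
    ``ratio_a_over_b`` (NaN where set B has no reads in the class).
    """
    if not set_a or not set_b:
        raise ValueError("both gene sets must be non-empty")
    by_gene = {v.gene_id: v for v in vectors}

    def profile(gene_set: set[str], label: str) -> dict[FeatureClass, float]:
        totals = {cls: 0 for cls in ASSIGNED_CLASSES}
        for gid in gene_set:
            v = by_gene.get(gid)
            if v is None:
                continue
            for cls in ASSIGNED_CLASSES:
                totals[cls] += v.counts[cls]
        grand = sum(totals.values())
        if grand == 0:
            raise ValueError(f"gene set {label!r} has zero allocated reads")
        return {cls: 100.0 * totals[cls] / grand for cls in ASSIGNED_CLASSES}

    pa = profile(set_a, "a")
    pb = profile(set_b, "b")
    rows = {
        cls.value: {
            "pct_a": pa[cls],
            "pct_b": pb[cls],
            "ratio_a_over_b": pa[cls] / pb[cls] if pb[cls] > 0 else float("nan"),
        }
        for cls in ASSIGNED_CLASSES
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def venn_counts(
    candidates: set[str],
    changed_per_mutant: Mapping[str, set[str]],
) -> dict[str, int]:
    """Counts per region of the three-set diagram (candidates x two mutants).

    ``changed_per_mutant`` maps mutant name to the genes passing the fold
    change cut in that mutant.  Keys of the result name the membership
    pattern, e.g. ``"candidates&nrpd1&nrpe1"`` for the triple intersection.
    """
    names = ["candidates", *changed_per_mutant]
    sets = [candidates, *changed_per_mutant.values()]
    out: dict[str, int] = {}
    universe = set().union(*sets)
    for gene in universe:
        membership = [name for name, s in zip(names, sets) if gene in s]
        key = "&".join(membership)
        out[key] = out.get(key, 0) + 1
    return out
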