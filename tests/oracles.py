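"""Independent brute-force reference implementations used as test oracles.

These deliberately use different mechanics from the package (per-base array
painting, regex scans, union-find clustering, naive sliding windows) so that
agreement is meaningful.
"""

from __future__ import annotations

import re

import numpy as np

from rddmap.model import FeatureClass, GeneModel, Strand

CLASS_CODE = {
    FeatureClass.UP2K: 0,
    FeatureClass.UTR5: 1,
    FeatureClass.CDS: 2,
    FeatureClass.INTRON: 3,
    FeatureClass.UTR3: 4,
    FeatureClass.DOWN2K: 5,
}
UNASSIGNED = -1


def paint_feature_arrays(
    genes: list[GeneModel], flank: int, chrom_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-base (gene index, feature class code) labels for one chromosome.

    Rules painted directly onto arrays: bodies claimed longest-first (ties by
    start), CDS > UTR > intron inside a body, flanks filling the gaps between
    body blocks up to `flank` bases and never past the gap midpoint.
    """
    owner = np.full(chrom_len, UNASSIGNED, dtype=np.int32)
    cls = np.full(chrom_len, UNASSIGNED, dtype=np.int8)

    order = sorted(
        range(len(genes)),
        key=lambda i: (-len(genes[i].body), genes[i].body.start, genes[i].gene_id),
    )
    for gi in order:
        g = genes[gi]
        body = slice(g.body.start, g.body.end)
        free = owner[body] == UNASSIGNED
        # internal classes for the full body, then masked by free bases
        internal = np.full(len(g.body), CLASS_CODE[FeatureClass.INTRON], dtype=np.int8)
        minus = g.strand is Strand.MINUS
        if g.cds:
            cds_lo = min(c.start for c in g.cds)
            cds_hi = max(c.end for c in g.cds)
            left = FeatureClass.UTR3 if minus else FeatureClass.UTR5
            right = FeatureClass.UTR5 if minus else FeatureClass.UTR3
            for e in g.exons:
                pieces = _subtract(e.start, e.end, [(c.start, c.end) for c in g.cds])
                for s, epc in pieces:
                    if epc <= cds_lo:
                        label = left
                    elif s >= cds_hi:
                        label = right
                    else:  # exonic non-CDS between CDS bounds: nearer edge, tie 5'
                        to_left = s - cds_lo
                        to_right = cds_hi - epc
                        if to_left < to_right or (to_left == to_right and not minus):
                            label = left
                        else:
                            label = right
                    internal[s - g.body.start : epc - g.body.start] = CLASS_CODE[label]
            for c in g.cds:
                internal[c.start - g.body.start : c.end - g.body.start] = CLASS_CODE[
                    FeatureClass.CDS
                ]
        else:
            for e in g.exons:
                internal[e.start - g.body.start : e.end - g.body.start] = CLASS_CODE[
                    FeatureClass.UTR5
                ]
        owner_slice = owner[body]
        cls_slice = cls[body]
        owner_slice[free] = gi
        cls_slice[free] = internal[free]

    # flanks: scan unowned runs between body blocks
    body_mask = owner != UNASSIGNED
    runs = _unowned_runs(body_mask)
    for a, b in runs:
        left_gene = owner[a - 1] if a > 0 else UNASSIGNED
        right_gene = owner[b] if b < chrom_len else UNASSIGNED
        if left_gene != UNASSIGNED and right_gene != UNASSIGNED:
            split = a + (b - a) // 2
            le = min(a + flank, split)
            rs = max(split, b - flank)
        elif left_gene != UNASSIGNED:
            le, rs = min(a + flank, b), b
        elif right_gene != UNASSIGNED:
            le, rs = a, max(a, b - flank)
        else:
            continue
        if left_gene != UNASSIGNED and a < le:
            g = genes[left_gene]
            fc = (
                FeatureClass.UP2K
                if g.strand is Strand.MINUS
                else FeatureClass.DOWN2K
            )
            owner[a:le] = left_gene
            cls[a:le] = CLASS_CODE[fc]
        if right_gene != UNASSIGNED and rs < b:
            g = genes[right_gene]
            fc = (
                FeatureClass.DOWN2K
                if g.strand is Strand.MINUS
                else FeatureClass.UP2K
            )
            owner[rs:b] = right_gene
            cls[rs:b] = CLASS_CODE[fc]
    return owner, cls


def _subtract(s: int, e: int, blockers: list[tuple[int, int]]) -> list[tuple[int, int]]:
    pieces = []
    cursor = s
    for bs, be in sorted(blockers):
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


def _unowned_runs(body_mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    n = len(body_mask)
    i = 0
    while i < n:
        if not body_mask[i]:
            j = i
            while j < n and not body_mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def regex_context_scan(seq: str) -> dict[tuple[int, str], str]:
    """Cytosine contexts on both strands via regex lookahead scans."""
    seq = seq.upper()
    n = len(seq)
    out: dict[tuple[int, str], str] = {}
    for i in [m.start() for m in re.finditer("C", seq)]:
        out[(i, "+")] = "undefined"
    for pattern, ctx in (("C(?=G)", "CG"), ("C(?=[ACT]G)", "CHG"), ("C(?=[ACT][ACT])", "CHH")):
        for m in re.finditer(f"(?={pattern})", seq):
            out[(m.start(), "+")] = ctx
    rc = seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
    for i in [m.start() for m in re.finditer("C", rc)]:
        out[(n - 1 - i, "-")] = "undefined"
    for pattern, ctx in (("C(?=G)", "CG"), ("C(?=[ACT]G)", "CHG"), ("C(?=[ACT][ACT])", "CHH")):
        for m in re.finditer(f"(?={pattern})", rc):
            out[(n - 1 - m.start(), "-")] = ctx
    return out


def union_find_clusters(
    intervals: list[tuple[int, int]], max_gap: int
) -> list[list[int]]:
    """Single-linkage clustering of same-chromosome intervals by gap distance."""
    n = len(intervals)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            s1, e1 = intervals[i]
            s2, e2 = intervals[j]
            gap = max(s1, s2) - min(e1, e2)
            if gap <= max_gap:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return list(clusters.values())


def naive_hamming_hit(srna: str, locus: str, max_mismatch: int) -> bool:
    """Sliding-window Hamming scan, forward and reverse complement."""
    rc = srna.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
    k = len(srna)
    for probe in (srna, rc):
        for i in range(len(locus) - k + 1):
            mm = sum(1 for a, b in zip(probe, locus[i : i + k]) if a != b)
            if mm <= max_mismatch:
                return True
    return False
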