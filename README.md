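# rddmap

Tools for turning AGO4 RNA-immunoprecipitation sequencing data into
RNA-directed DNA methylation (RdDM) target-gene calls.

In plants, RdDM silences transposons and regulates protein-coding genes: a
24-nt siRNA loaded on ARGONAUTE 4 (AGO4) is tethered to chromatin by a long
noncoding scaffold RNA, and the DRM2 methyltransferase then methylates
cytosines in all three sequence contexts (CG, CHG and CHH, H ∈ {A,C,T}).
Sequencing the RNA bound to AGO4 reveals where these scaffold lncRNAs come
from; intersecting that evidence with expression changes in RdDM polymerase
mutants (*nrpd1* for POL IV, *nrpe1* for POL V) identifies genes the pathway
represses (up-regulated in the mutants) and, more surprisingly, genes it
activates (down-regulated in the mutants).

`rddmap` implements that integrative analysis as a tested library + CLI:

* **read filtering** — length ≥ 30 nt (to exclude the siRNA fraction),
  mapping acceptance (identity ≥ 80 % over ≥ 70 % of the read, ≤ 20
  placements so repeat-derived reads survive), and the global strand flip
  required by template-switch library construction;
* **once-only feature allocation** — every nuclear base carries at most one
  `(gene, feature)` label (5′/3′ 2-kb flank, 5′/3′ UTR, CDS, intron); gene
  bodies beat neighbouring flanks, intergenic gaps are split at their
  midpoint, and each read is assigned by its midpoint base, so reads are
  never double-counted;
* **lncRNA locus assembly** — coverage islands (reads separated by ≤ 50 bp),
  500-bp extension, binary overlap fractions against external interval sets
  (ChIP peaks, transposons, hypomethylated regions) with a size-matched
  randomization null and empirical p-value;
* **small-RNA mapping** — ungapped Hamming matching of sRNAs (or their
  reverse complements) onto locus sequences with ≤ 2 mismatches;
* **bisulphite clone analysis** — cytosine context enumeration on both
  strands, per-site methylation levels from ~16 clones per genotype,
  conversion-efficiency control, and hypo/hyper calls between genotypes;
* **target classification** — genes with ≥ 50 allocated reads intersected
  with linear fold changes from two mutants (≥ 2-fold in *both* → repressed;
  ≤ 0.5-fold in both → activated), plus feature-profile comparison between
  the two sets;
* **a synthetic-data generator** — genomes with organelles (ChrC/ChrM),
  annotations, class-mixture reads, planted repressed/activated genes and
  per-context bisulphite clones, so the entire pipeline runs and is tested
  without any external download.

## Worked example

Run the full pipeline on synthetic data:

```bash
rddmap run --outdir demo_run --seed 1
```

This simulates a 540-kb genome (two nuclear chromosomes plus ChrC/ChrM), 34
genes and 20,000 reads, then filters, allocates, assembles, overlaps,
classifies and runs the clone analysis.  The run directory contains every
stage's output (`reads.filtered.tsv`, `gene_counts.tsv`, `loci.bed`,
`overlap.json`, `genes_repressed.txt`, …) and a `summary.json`.  Key lines
of the printed summary for seed 1:

```
"filter":   {"input_reads": 20000, "after_length_filter": 17944,
             "after_acceptance_filter": 16158}
"allocate": {"feature_pct": {"up2k": 47.7, "down2k": 22.0, "intron": 11.3,
             "cds": 12.2, "utr5": 4.6, "utr3": 2.1}, ...}
"assemble": {"n_loci": 647}
"overlap":  {"te_overlap_fraction": 0.151,
             "te_overlap_fraction_extended": 0.218,
             "null_mean": 0.125, "empirical_p": 0.030}
"classify": {"n_candidates": 34, "n_repressed": 4, "n_activated": 6}
"meth":     {"CHH": {"hypo": 63, "hyper": 1, "unchanged": 2}, ...}
```

Reading it: ~10 % of reads fail the length filter and ~10 % the mapping
acceptance, as planted.  Allocated reads are dominated by the 5′ flank
(47.7 %) — the simulated library's flank bias.  647 lncRNA loci are
assembled; 15.1 % touch a transposon, rising to 21.8 % after 500-bp
extension, against a 12.5 % size-matched random expectation (p ≈ 0.03).
The classifier recovers exactly the 4 planted repressed and 6 planted
activated genes, and the clone comparison calls 63/66 CHH sites
hypo-methylated in the simulated mutant, the expected signature of losing
the pathway.  `accounting.txt` holds the library-level read accounting
(total / nuclear / organellar percentages).

Every stage is also exposed on its own (`rddmap simulate|filter|allocate|
assemble|overlap|srna-map|classify|meth`) and as plain library functions.

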