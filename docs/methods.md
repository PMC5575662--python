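# Methods

This note documents the models, conventions and numerical choices behind
`rddmap`, what the synthetic-data generator does and does not emulate, and
the limitations a user should know about.

## Coordinates and annotation model

All internal coordinates are 0-based, half-open, on the forward reference
strand.  GFF3 (1-based inclusive) is converted at the I/O boundary only;
BED is used natively.  A gene is collapsed to one structure: its exons are
the union over isoforms, its CDS likewise, and its body spans
`min(exon start) .. max(exon end)`; everything inside the body but outside
an exon is intron.  The seven-biotype vocabulary (protein_coding,
transposable_element, pseudogene, ncRNA, miRNA, snoRNA, tRNA) is fixed;
unrecognised GFF3 feature types are mapped to ncRNA with a warning.

## Read filters

Three filters run before any counting, all with inclusive thresholds:

| parameter | default | meaning |
|---|---|---|
| `min_read_len` | 30 nt | drops the 24-nt siRNA fraction after trimming |
| `min_identity` | 0.80 | matching fraction inside the aligned segment (tolerates ecotype SNPs) |
| `min_aligned_fraction` | 0.70 | fraction of the read that is aligned |
| `max_hits` | 20 | multi-mappers retained to keep repeat-derived RNA |

Identity and aligned fraction are treated as independent attributes of an
alignment record; whether the upstream aligner counted indels toward
"similarity" is aligner-specific and outside this package's control.  The
global strand flip (`orient_reads`) models template-switch library
chemistry, which sequences the strand complementary to the captured RNA; it
is an involution and does not move coordinates.

## Once-only feature allocation

The allocation index labels every nuclear base with at most one
`(gene, feature)`:

* **Bodies first.** Overlapping gene bodies are resolved by "longer gene
  wins", ties to the smaller start coordinate.  Inside a body, CDS beats
  UTR beats intron.  5′/3′ UTR sides follow the gene's strand.  Two corner
  cases needed a rule the data model does not forbid: exonic non-CDS bases
  strictly between the CDS bounds are given the UTR of the nearer CDS edge
  (tie → 5′), and genes without any CDS (ncRNA, TE, pseudogene) have all
  exonic bases labeled 5′ UTR — the whole transcript is untranslated and
  the enumeration has no separate noncoding-exon class.
* **Flanks in the gaps.** Each gap between consecutive body blocks is split
  at `a + floor((b−a)/2)`; the base at the split belongs to the downstream
  gene.  Each side's flank is capped at `flank` (2 kb) bases.  Flank class
  (5′ vs 3′) follows the owning gene's strand; unstranded genes are treated
  as plus-strand.
* **Reads by midpoint.** A read contributes exactly 1 to the territory of
  its midpoint base `(start+end)//2`.  This makes "each read counted once"
  exact, gives a well-defined answer for reads spanning a territory
  boundary, and is insensitive to read length.  Read strand is ignored for
  territory assignment — territories are strand-labeled by the owning gene
  only.

Multi-mapped reads contribute once per placement record; per-gene vectors
additionally carry a distinct-read-id count.  The ≥ 50-read candidate
threshold operates on placements, consistent with keeping multi-mappers to
preserve repeat signal.

The genome-category view (protein-coding / transposon / other-genic /
intergenic) uses the same midpoint rule with the priority protein_coding >
transposon > other > intergenic; repeat association is tallied
independently because a read can be both genic and repeat-derived.

The heatmap matrix is `log10(count+1)` per gene × feature, divided by the
row maximum; rows with no reads are dropped, values lie in [0, 1].

## Locus assembly and overlap statistics

Loci are coverage islands: maximal runs of reads in which consecutive
placements are separated by at most `max_gap` (default 50 bp; overlapping
or abutting reads always merge), keeping islands with at least `min_reads`
(default 2) supporting reads.  This is a deliberate, fully specified
replacement for a heuristic transcript assembler: islands are order-
invariant, parameter-sparse and exactly testable against single-linkage
clustering.

Overlap between interval sets is binary per query interval (≥ 1 shared
base, half-open semantics: abutting intervals do not overlap).  The null
model re-places intervals of exactly the query's lengths uniformly at
random — chromosome chosen proportional to length, start uniform so the
interval fits — and reports the empirical p-value
`(1 + #{null ≥ observed}) / (n_reps + 1)`, which can never be 0.  With
point-like queries the expected null fraction equals the subject's coverage
fraction, which is the calibration the test suite checks at 1000
replicates.  Locus extension (default 500 bp per side) clips at chromosome
ends and does not merge loci, so the overlap fraction is monotone
non-decreasing under extension.

sRNA-to-locus mapping is ungapped Hamming matching of the sRNA or its
reverse complement with ≤ `max_srna_mismatch` (default 2) mismatches.
Probes ≤ 32 nt over ACGT are 2-bit packed and compared to every locus
window by XOR/popcount; anything else falls back to an explicit window
comparison.  Both paths are checked against a naive sliding-window scan.

## Bisulphite clone model

Contexts are assigned from the reference alone: a plus-strand C is CG, CHG
or CHH by its next two downstream bases; a minus-strand C (a reference G)
symmetrically by the complemented upstream bases.  Sites lacking the
required bases, or with an N among them, are UNDEFINED and excluded from
all counts.  Every plus-strand CG has a minus-strand partner at +1 — a
property test.

Clones are assumed ungapped, full-length copies of the amplicon in
reference orientation (the normal situation for short cloned PCR products;
indel-containing clones must be rejected upstream).  At a site, C means
methylated (protected), T converted; on the minus strand G/A respectively;
any other base (SNP, sequencing error) is excluded from that clone's
total.  Conversion efficiency is the converted fraction of cytosine
observations in a control region known to be unmethylated.

Genotype comparison calls a site hypo-/hyper-methylated when the level
difference (mutant − wild type, in absolute methylated fraction) reaches
`min_delta`, default 0.1 — a round, exposed default chosen because clone
counts of ~16 resolve level differences of about 1/16.  Both the
percentage-point delta and the per-site levels are reported, so relative
reductions can be derived by the user.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of `(spec, seed)` (numpy `default_rng`
seeded per stage).  The defaults encode the emulated study conditions:

* **Genome** — AT-rich (32/18/18/32) random nuclear chromosomes
  (300 + 200 kb) plus ChrC/ChrM organelles; repeat intervals placed until
  their union reaches `repeat_density` (0.15) of each nuclear chromosome,
  half of them marked as transposons.
* **Annotation** — genes apportioned to chromosomes by length (largest
  remainder), ≥ 2 exons, CDS flanked by UTRs, bodies separated by ≥ 5 kb so
  2-kb flanks and an intergenic gap both exist; single-exon TE genes placed
  inside transposon intervals.
* **Reads** — class mixture over {5′ flank, 3′ flank, gene body, other
  intergenic, transposon, organelle}, default
  (0.300, 0.140, 0.190, 0.328, 0.039, 0.003): ~0.3 % organellar
  contamination and an intergenic/flank-dominated nuclear profile matching
  an AGO4-IP library.  Class territories are made disjoint (body > 5′
  flank > 3′ flank > transposon) so the planted mixture is exactly
  recoverable by recounting midpoints.  Read lengths are uniform 30–100 nt
  (the post-trim distribution of a 100-bp single-end run is not otherwise
  modeled), with 10 % planted short (< 30 nt) and 10 % planted to fail the
  acceptance filter.  Alignment attributes are simulated, not recomputed
  from sequence: the artifact tests allocation, not alignment.
* **Expression** — planted repressed genes get `planted_fc` (default 4) ×
  log-normal noise in every mutant column, activated genes the reciprocal;
  background genes draw log2 fold changes from N(0, 0.25).  Planted values
  are not clamped at the threshold, so recovery is statistically ~1 rather
  than exactly 1.
* **Clones** — per-context methylation probabilities (wild-type default
  CG 0.9 / CHG 0.7 / CHH 0.4; mutant 0.85 / 0.3 / 0.1, the CHH-dominant
  loss expected when the scaffold polymerase is absent), conversion rate
  0.99; UNDEFINED-context cytosines follow the CHH probability.
* **sRNAs** — 24-mers sampled from locus territory, ≤ 1 planted mismatch,
  half reverse-complemented.

Not emulated: sequencing errors and quality scores, adapter content
(trimming is reduced to the length filter), alignment ambiguity (each read
has one placement record; `n_hits` is an attribute), splicing, isoform
diversity, and chromatin context.  Passing tests therefore demonstrate the
correctness of the accounting, allocation, overlap, classification and
clone arithmetic under known ground truth — not robustness to alignment or
library-preparation artifacts in real data.

## Pipeline and determinism

`run_pipeline` executes simulate (optional) → filter → allocate → assemble
→ overlap → sRNA-map → classify → meth, records per-stage counts and a
SHA-256 hash of the configuration, and is byte-identical across re-runs
with the same config and seed.  Stages degrade gracefully: no expression
table skips classification with a notice; no transposon set skips the
overlap test.  Library-level accounting prints percentages at integer
precision (one decimal below 1 %), the convention used for sequencing
library summary tables.

The test suite and the acceptance script run at desk scale by design:
toy genomes ≤ 100 kb for the base-exact territory checks, 20,000-read
demo libraries, 1000-replicate nulls, 10 × 500-gene classification
experiments.  These sizes give the statistical checks comfortable margins
(3 standard errors or better) while keeping the whole suite in the
tens-of-seconds range.

## Known limitations

* The coverage-island assembler is not a transcript model: no splicing, no
  strand-specific locus calling, and locus counts depend on `max_gap` and
  sequencing depth, so absolute locus numbers are not comparable to
  assembler-based counts on real data.
* Overlap significance uses a single global randomization null; no
  GC/chromatin-matched shuffling and no multiplicity correction across
  many subject sets.
* Classification takes fold changes as given; it performs no expression
  statistics, so noise in the expression table propagates directly.
* The clone model rejects indels rather than aligning them; amplicons with
  real indel variation need upstream alignment.
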