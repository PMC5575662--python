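"""Once-only feature allocation: midpoint rules, conservation, oracle checks."""

import numpy as np
import pytest

from rddmap.allocation import (
    allocate_reads,
    build_feature_index,
    feature_distribution,
    genomic_category_distribution,
    heatmap_matrix,
)
from rddmap.model import (
    ASSIGNED_CLASSES,
    Biotype,
    FeatureClass,
    FeatureCountVector,
    GenomicInterval,
)
from rddmap.simulate import SimulationSpec, generate_annotation, generate_genome, simulate_rip_reads

from conftest import make_gene, make_read, random_toy_annotation
from oracles import CLASS_CODE, UNASSIGNED, paint_feature_arrays


class TestIntergenicMidpoint:
    def setup_method(self):
        # gene A ends at 1000, gene B starts at 5000, both plus strand
        self.genes = [
            make_gene("A", "Chr1", 200, 1000, "+"),
            make_gene("B", "Chr1", 5000, 5800, "+"),
        ]
        self.index = build_feature_index(self.genes, flank=2000,
                                         chrom_lengths={"Chr1": 10_000})

    def test_split_point_at_gap_midpoint(self):
        assert self.index.lookup("Chr1", 2999) == ("A", FeatureClass.DOWN2K)
        assert self.index.lookup("Chr1", 3000) == ("B", FeatureClass.UP2K)

    def test_flank_capped_in_wide_gap(self):
        genes = [
            make_gene("A", "Chr1", 200, 1000, "+"),
            make_gene("B", "Chr1", 7000, 7800, "+"),  # gap of 6000
        ]
        index = build_feature_index(genes, flank=2000, chrom_lengths={"Chr1": 10_000})
        assert index.lookup("Chr1", 2999) == ("A", FeatureClass.DOWN2K)
        assert index.lookup("Chr1", 3000) is None          # unassigned middle
        assert index.lookup("Chr1", 4999) is None
        assert index.lookup("Chr1", 5000) == ("B", FeatureClass.UP2K)

    def test_swapping_gene_labels_mirrors_split(self):
        mirrored = [
            make_gene("B", "Chr1", 200, 1000, "+"),
            make_gene("A", "Chr1", 5000, 5800, "+"),
        ]
        index = build_feature_index(mirrored, flank=2000,
                                    chrom_lengths={"Chr1": 10_000})
        assert index.lookup("Chr1", 2999) == ("B", FeatureClass.DOWN2K)
        assert index.lookup("Chr1", 3000) == ("A", FeatureClass.UP2K)

    def test_minus_strand_gene_flank_orientation(self):
        genes = [make_gene("A", "Chr1", 5000, 6000, "-")]
        index = build_feature_index(genes, flank=2000, chrom_lengths={"Chr1": 10_000})
        # 5' flank of a minus gene lies at higher coordinates
        assert index.lookup("Chr1", 6500) == ("A", FeatureClass.UP2K)
        assert index.lookup("Chr1", 4500) == ("A", FeatureClass.DOWN2K)


class TestBodyPriority:
    def test_intron_beats_neighbour_upstream_flank(self):
        # base inside A's intron that is also within 2 kb upstream of B
        genes = [
            make_gene("A", "Chr1", 1000, 4000, "+",
                      exons=[(1000, 1500), (3500, 4000)],
                      cds=[(1100, 1500), (3500, 3900)]),
            make_gene("B", "Chr1", 4500, 5500, "+"),
        ]
        index = build_feature_index(genes, flank=2000, chrom_lengths={"Chr1": 10_000})
        assert index.lookup("Chr1", 3000) == ("A", FeatureClass.INTRON)

    def test_cds_utr_intron_within_gene(self):
        gene = make_gene("A", "Chr1", 1000, 2000, "+",
                         exons=[(1000, 1400), (1600, 2000)],
                         cds=[(1200, 1400), (1600, 1900)])
        index = build_feature_index([gene], flank=2000, chrom_lengths={"Chr1": 5000})
        assert index.lookup("Chr1", 1100) == ("A", FeatureClass.UTR5)
        assert index.lookup("Chr1", 1300) == ("A", FeatureClass.CDS)
        assert index.lookup("Chr1", 1500) == ("A", FeatureClass.INTRON)
        assert index.lookup("Chr1", 1950) == ("A", FeatureClass.UTR3)


class TestAllocateReads:
    def test_conservation_of_read_count(self):
        rng = np.random.default_rng(5)
        genes = random_toy_annotation(rng, "Chr1", 50_000)
        index = build_feature_index(genes, flank=2000, chrom_lengths={"Chr1": 50_000})
        reads = [
            make_read("Chr1", int(s), int(s) + 60, read_id=f"r{i}")
            for i, s in enumerate(rng.integers(0, 49_900, size=100))
        ]
        vectors, unassigned = allocate_reads(reads, index)
        assert sum(v.total for v in vectors) + unassigned == 100

    def test_midpoint_decides_for_junction_spanning_read(self):
        gene = make_gene("A", "Chr1", 1000, 2000, "+",
                         exons=[(1000, 1500), (1700, 2000)],
                         cds=[(1100, 1500), (1700, 1900)])
        index = build_feature_index([gene], flank=2000, chrom_lengths={"Chr1": 5000})
        # read spans the exon/intron junction at 1500; midpoint 1460 in CDS
        read = make_read("Chr1", 1400, 1520)
        vectors, _ = allocate_reads([read], index)
        assert vectors[0].counts[FeatureClass.CDS] == 1

    def test_unknown_chromosome_counts_unassigned_with_warning(self):
        index = build_feature_index(
            [make_gene("A", "Chr1", 1000, 2000)], chrom_lengths={"Chr1": 5000}
        )
        with pytest.warns(UserWarning, match="unknown chromosome"):
            vectors, unassigned = allocate_reads([make_read("ChrX", 0, 50)], index)
        assert (vectors, unassigned) == ([], 1)

    def test_matches_per_base_painting_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            clen = int(rng.integers(20_000, 60_000))
            genes = random_toy_annotation(rng, "Chr1", clen)
            index = build_feature_index(genes, flank=2000,
                                        chrom_lengths={"Chr1": clen})
            owner, cls = paint_feature_arrays(genes, 2000, clen)
            reads = [
                make_read("Chr1", int(s), min(int(s) + 70, clen), read_id=f"r{i}")
                for i, s in enumerate(rng.integers(0, clen - 70, size=50))
            ]
            vectors, unassigned = allocate_reads(reads, index)
            # oracle recount per read midpoint
            expected: dict[tuple[str, FeatureClass], int] = {}
            n_un = 0
            for r in reads:
                mid = r.placement.midpoint
                if owner[mid] == UNASSIGNED:
                    n_un += 1
                    continue
                gid = genes[owner[mid]].gene_id
                fc = next(k for k, v in CLASS_CODE.items() if v == cls[mid])
                expected[(gid, fc)] = expected.get((gid, fc), 0) + 1
            got = {
                (v.gene_id, fc): v.counts[fc]
                for v in vectors
                for fc in ASSIGNED_CLASSES
                if v.counts[fc]
            }
            assert got == expected
            assert unassigned == n_un


class TestTerritoryPartition:
    def test_index_equals_painted_arrays_base_by_base(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            clen = int(rng.integers(10_000, 40_000))
            genes = random_toy_annotation(rng, "Chr1", clen)
            index = build_feature_index(genes, flank=2000,
                                        chrom_lengths={"Chr1": clen})
            owner, cls = paint_feature_arrays(genes, 2000, clen)
            got_owner = np.full(clen, UNASSIGNED, dtype=np.int32)
            got_cls = np.full(clen, UNASSIGNED, dtype=np.int8)
            idx_by_id = {g.gene_id: i for i, g in enumerate(genes)}
            for iv, gid, fc in index.territories():
                assert got_owner[iv.start : iv.end].max(initial=UNASSIGNED) == UNASSIGNED, (
                    "territories overlap"
                )
                got_owner[iv.start : iv.end] = idx_by_id[gid]
                got_cls[iv.start : iv.end] = CLASS_CODE[fc]
            assert np.array_equal(owner, got_owner)
            assert np.array_equal(cls, got_cls)


class TestCategoryDistribution:
    def test_all_reads_in_gene_bodies(self):
        genes = [make_gene("A", "Chr1", 1000, 3000)]
        reads = [make_read("Chr1", 1500, 1560, read_id=f"r{i}") for i in range(10)]
        dist = genomic_category_distribution(reads, genes)
        assert dist.fractions["protein_coding"] == 1.0
        assert sum(dist.fractions.values()) == pytest.approx(1.0)

    def test_te_overlapping_coding_gene_counts_as_protein_coding(self):
        genes = [
            make_gene("A", "Chr1", 1000, 3000),
            make_gene("te", "Chr1", 1500, 2500, biotype=Biotype.TRANSPOSABLE_ELEMENT),
        ]
        reads = [make_read("Chr1", 1900, 1960)]
        dist = genomic_category_distribution(reads, genes)
        assert dist.fractions["protein_coding"] == 1.0
        assert dist.fractions["transposon"] == 0.0

    def test_repeat_association_is_independent(self):
        genes = [make_gene("A", "Chr1", 1000, 3000)]
        repeats = [GenomicInterval("Chr1", 1800, 2200)]
        reads = [make_read("Chr1", 1900, 2000), make_read("Chr1", 1000, 1100)]
        dist = genomic_category_distribution(reads, genes, repeats)
        assert dist.fractions["protein_coding"] == 1.0
        assert dist.repeat_associated == 0.5

    def test_planted_mixture_recovered(self):
        spec = SimulationSpec(
            chromosome_lengths={"Chr1": 200_000, "Chr2": 150_000},
            include_organelles=False,
            organelle_lengths={},
            n_genes=12, n_te_genes=0,
            read_class_mix={
                "gene_flank_5": 0.0, "gene_flank_3": 0.0, "gene_body": 0.2,
                "intergenic_other": 0.7, "transposon": 0.1, "organelle": 0.0,
            },
            short_read_fraction=0.0, fail_fraction=0.0, seed=9,
        )
        genome = generate_genome(spec)
        ann = generate_annotation(genome, spec)
        reads = simulate_rip_reads(genome, ann, spec, 10_000)
        dist = genomic_category_distribution(
            reads, ann, genome.repeats, genome.transposons
        )
        assert dist.fractions["protein_coding"] == pytest.approx(0.2, abs=0.02)
        assert dist.fractions["transposon"] == pytest.approx(0.1, abs=0.02)
        assert dist.fractions["intergenic"] + dist.fractions["other_genic"] == (
            pytest.approx(0.7, abs=0.02)
        )


class TestFeatureDistribution:
    def test_single_class_and_normalization(self):
        v = FeatureCountVector("g", counts={FeatureClass.UP2K: 10})
        dist = feature_distribution([v])
        assert dist[FeatureClass.UP2K] == 100.0
        assert sum(dist.values()) == pytest.approx(100.0)

    def test_zero_reads_is_an_error(self):
        with pytest.raises(ValueError):
            feature_distribution([FeatureCountVector("g")])

    def test_planted_flank_shares_recovered(self):
        spec = SimulationSpec(
            chromosome_lengths={"Chr1": 250_000},
            include_organelles=False,
            organelle_lengths={},
            n_genes=12, n_te_genes=0,
            read_class_mix={
                "gene_flank_5": 0.4, "gene_flank_3": 0.2, "gene_body": 0.4,
                "intergenic_other": 0.0, "transposon": 0.0, "organelle": 0.0,
            },
            short_read_fraction=0.0, fail_fraction=0.0, seed=13,
        )
        genome = generate_genome(spec)
        ann = generate_annotation(genome, spec)
        reads = simulate_rip_reads(genome, ann, spec, 10_000)
        index = build_feature_index(ann, flank=spec.flank,
                                    chrom_lengths=genome.lengths)
        vectors, _ = allocate_reads(reads, index)
        dist = feature_distribution(vectors)
        assert dist[FeatureClass.UP2K] == pytest.approx(40.0, abs=2.0)
        assert dist[FeatureClass.DOWN2K] == pytest.approx(20.0, abs=2.0)


class TestHeatmapMatrix:
    def test_row_max_normalization(self):
        v = FeatureCountVector("g", counts={FeatureClass.UP2K: 9})
        row = heatmap_matrix([v]).loc["g"]
        assert row["up2k"] == 1.0
        assert row.drop("up2k").eq(0).all()

    def test_min_total_threshold_is_inclusive(self):
        v49 = FeatureCountVector("a", counts={FeatureClass.CDS: 49})
        v50 = FeatureCountVector("b", counts={FeatureClass.CDS: 50})
        mat = heatmap_matrix([v49, v50], min_total=50)
        assert list(mat.index) == ["b"]

    def test_uniform_counts_give_constant_row(self):
        v = FeatureCountVector("g", counts={c: 7 for c in ASSIGNED_CLASSES})
        row = heatmap_matrix([v]).loc["g"]
        assert row.eq(1.0).all()

    def test_values_bounded_and_empty_selection_warns(self):
        v = FeatureCountVector("g", counts={FeatureClass.UP2K: 3,
                                            FeatureClass.INTRON: 30})
        mat = heatmap_matrix([v])
        assert ((mat >= 0) & (mat <= 1)).all().all()
        with pytest.warns(UserWarning):
            empty = heatmap_matrix([v], min_total=1000)
        assert empty.empty
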