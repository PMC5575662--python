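"""Generators: determinism, planted structure, and statistical recovery."""

import numpy as np
import pytest
from scipy import stats

from rddmap.model import Biotype, GeneModel, GenomicInterval, Strand
from rddmap.simulate import (
    SimulationSpec,
    SizingError,
    generate_annotation,
    generate_genome,
    simulate_bisulphite_clones,
    simulate_expression_table,
    simulate_rip_reads,
)


def coverage_by_base_counting(intervals, chrom_len):
    """Brute-force repeat coverage: paint a boolean base array."""
    mask = np.zeros(chrom_len, dtype=bool)
    for iv in intervals:
        mask[iv.start : iv.end] = True
    return mask.mean()


class TestGenerateGenome:
    def test_fixed_seed_is_byte_identical(self, small_spec):
        a = generate_genome(small_spec)
        b = generate_genome(small_spec)
        assert a.sequences == b.sequences
        assert a.repeats == b.repeats and a.transposons == b.transposons

    def test_zero_repeat_density_gives_empty_set(self, small_spec):
        spec = SimulationSpec(
            chromosome_lengths={"Chr1": 50_000}, repeat_density=0.0, seed=1
        )
        assert generate_genome(spec).repeats == []

    def test_repeat_coverage_close_to_density(self):
        spec = SimulationSpec(
            chromosome_lengths={"Chr1": 1_000_000},
            include_organelles=False,
            organelle_lengths={},
            repeat_density=0.2,
            seed=5,
        )
        genome = generate_genome(spec)
        cov = coverage_by_base_counting(
            [iv for iv in genome.repeats if iv.chrom == "Chr1"], 1_000_000
        )
        assert cov == pytest.approx(0.2, abs=0.05)

    def test_organelles_present_and_named(self, small_spec):
        genome = generate_genome(small_spec)
        assert set(genome.organelles) == {"ChrC", "ChrM"}


class TestGenerateAnnotation:
    def test_gene_count_and_minimum_spacing(self):
        spec = SimulationSpec(
            chromosome_lengths={"Chr1": 150_000},
            n_genes=10, n_te_genes=0, seed=2,
        )
        genome = generate_genome(spec)
        genes = sorted(generate_annotation(genome, spec), key=lambda g: g.body.start)
        assert len(genes) == 10
        for a, b in zip(genes, genes[1:]):
            assert b.body.start - a.body.end >= 5000
        for g in genes:
            assert len(g.exons) >= 2
            assert g.cds  # GeneModel validation guarantees CDS within exons

    def test_sizing_error_when_genome_too_small(self):
        spec = SimulationSpec(
            chromosome_lengths={"Chr1": 20_000}, n_genes=10, seed=2
        )
        genome = generate_genome(spec)
        with pytest.raises(SizingError):
            generate_annotation(genome, spec)

    def test_gene_density_proportional_to_chromosome_length(self):
        spec = SimulationSpec(
            chromosome_lengths={"Chr1": 300_000, "Chr2": 200_000, "Chr3": 100_000},
            n_genes=30, n_te_genes=0, seed=3,
        )
        genome = generate_genome(spec)
        genes = generate_annotation(genome, spec)
        counts = {c: sum(g.chrom == c for g in genes) for c in spec.chromosome_lengths}
        total_len = sum(spec.chromosome_lengths.values())
        for c, clen in spec.chromosome_lengths.items():
            expected = 30 * clen / total_len
            assert abs(counts[c] - expected) <= 0.2 * expected + 1

    def test_te_genes_inside_te_intervals(self, small_world):
        _, genome, annotation = small_world
        te_genes = [g for g in annotation
                    if g.biotype is Biotype.TRANSPOSABLE_ELEMENT]
        assert te_genes
        for g in te_genes:
            assert any(
                iv.chrom == g.chrom and iv.start <= g.body.start and g.body.end <= iv.end
                for iv in genome.transposons
            )


class TestSimulateReads:
    def test_fixed_seed_identical_reads(self, small_world):
        spec, genome, annotation = small_world
        a = simulate_rip_reads(genome, annotation, spec, 500)
        b = simulate_rip_reads(genome, annotation, spec, 500)
        assert a == b

    def test_pure_organelle_mix(self, small_world):
        spec, genome, annotation = small_world
        import dataclasses
        spec2 = dataclasses.replace(
            spec,
            read_class_mix={c: (1.0 if c == "organelle" else 0.0)
                            for c in spec.read_class_mix},
        )
        reads = simulate_rip_reads(genome, annotation, spec2, 300)
        assert {r.placement.chrom for r in reads} <= {"ChrC", "ChrM"}

    def test_organelle_class_without_organelles_is_an_error(self):
        spec = SimulationSpec(
            chromosome_lengths={"Chr1": 100_000},
            include_organelles=False,
            organelle_lengths={},
            n_genes=5, n_te_genes=0, seed=1,
        )
        genome = generate_genome(spec)
        annotation = generate_annotation(genome, spec)
        with pytest.raises(ValueError, match="organelle"):
            simulate_rip_reads(genome, annotation, spec, 10)

    def test_gene_body_fraction_recovered_by_recount(self):
        spec = SimulationSpec(
            chromosome_lengths={"Chr1": 250_000, "Chr2": 150_000},
            n_genes=14, n_te_genes=0,
            read_class_mix={
                "gene_flank_5": 0.2, "gene_flank_3": 0.1, "gene_body": 0.2,
                "intergenic_other": 0.45, "transposon": 0.047, "organelle": 0.003,
            },
            short_read_fraction=0.0, fail_fraction=0.0, seed=21,
        )
        genome = generate_genome(spec)
        annotation = generate_annotation(genome, spec)
        reads = simulate_rip_reads(genome, annotation, spec, 10_000)
        bodies = [g.body for g in annotation]
        in_body = sum(
            any(
                b.chrom == r.placement.chrom and b.start <= r.placement.midpoint < b.end
                for b in bodies
            )
            for r in reads
        )
        assert in_body / 10_000 == pytest.approx(0.2, abs=0.02)


def flat_annotation(n):
    """Cheap gene list (ids only matter) for expression simulation."""
    return [
        GeneModel(
            gene_id=f"g{i:04d}",
            biotype=Biotype.PROTEIN_CODING,
            body=GenomicInterval("Chr1", i * 10, i * 10 + 5, Strand.PLUS),
            exons=[GenomicInterval("Chr1", i * 10, i * 10 + 5, Strand.PLUS)],
        )
        for i in range(n)
    ]


class TestExpressionTable:
    def test_planted_values_without_noise(self):
        ann = flat_annotation(10)
        spec = SimulationSpec(
            planted_repressed={"g0000": 4.0},
            planted_activated={"g0001": 4.0},
            expression_noise_sd=0.0,
            seed=1,
        )
        table = simulate_expression_table(ann, spec)
        assert (table.loc["g0000"] == 4.0).all()
        assert (table.loc["g0001"] == 0.25).all()
        background = table.drop(["g0000", "g0001"])
        assert (background == 1.0).all().all()

    def test_planted_below_threshold_is_an_error(self):
        ann = flat_annotation(3)
        with pytest.raises(ValueError, match="threshold"):
            spec = SimulationSpec(planted_repressed={"g0000": 1.5}, seed=1)
            simulate_expression_table(ann, spec)

    def test_unknown_planted_gene_is_an_error(self):
        ann = flat_annotation(3)
        spec = SimulationSpec(planted_repressed={"nope": 4.0}, seed=1)
        with pytest.raises(ValueError, match="not annotated"):
            simulate_expression_table(ann, spec)

    def test_background_tail_matches_normal_oracle(self):
        ann = flat_annotation(5000)
        spec = SimulationSpec(expression_noise_sd=0.25, seed=8)
        table = simulate_expression_table(ann, spec)
        log2 = np.log2(table["nrpd1"].to_numpy())
        assert log2.mean() == pytest.approx(0.0, abs=0.02)
        assert log2.std() == pytest.approx(0.25, abs=0.02)
        # P(fold change >= 2 in one column) = Phi(-4): ~0.3 genes in 5000
        p_tail = stats.norm.sf(1.0, scale=0.25)
        expected = 5000 * p_tail
        assert (table["nrpd1"] >= 2.0).sum() <= expected + 4


class TestBisulphiteClones:
    region = "ACGTCATCCAGGTTACCGGATCCATTACGACCA"

    def test_full_methylation_reproduces_reference(self):
        spec = SimulationSpec(
            clone_meth_prob={"CG": 1.0, "CHG": 1.0, "CHH": 1.0},
            n_clones=4, seed=1,
        )
        clones = simulate_bisulphite_clones(self.region, spec)
        assert all(seq == self.region for _, seq, _ in clones)

    def test_no_methylation_full_conversion(self):
        spec = SimulationSpec(
            clone_meth_prob={"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
            n_clones=4, conversion_rate=1.0, seed=1,
        )
        for _, seq, _ in simulate_bisulphite_clones(self.region, spec):
            assert "C" not in seq[:-2] or all(
                b != "C" for i, b in enumerate(seq)
                if i < len(seq) - 2  # terminal Cs have undefined context too
            )
        # every plus-strand C converted, including undefined-context ones
        (_, seq, _) = simulate_bisulphite_clones(self.region, spec)[0]
        assert "C" not in seq

    def test_no_cytosine_region_warns_and_returns_reference(self):
        spec = SimulationSpec(n_clones=2, seed=1)
        with pytest.warns(UserWarning, match="no cytosines"):
            clones = simulate_bisulphite_clones("ATTA", spec)
        assert all(seq == "ATTA" for _, seq, _ in clones)

    def test_chh_level_matches_binomial_oracle(self):
        rng = np.random.default_rng(9)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        region = bases[
            rng.choice(4, size=800, p=[0.35, 0.15, 0.15, 0.35])
        ].tobytes().decode()
        spec = SimulationSpec(
            clone_meth_prob={"CG": 0.0, "CHG": 0.0, "CHH": 0.3},
            n_clones=16, conversion_rate=1.0, seed=4,
        )
        from rddmap.methylation import Context, clone_methylation_levels, enumerate_contexts

        clones = simulate_bisulphite_clones(region, spec)
        sites = enumerate_contexts(region)
        scored = clone_methylation_levels(
            sites, [(s, st) for _, s, st in clones], len(region)
        )
        chh = [s for s in scored
               if s.context is Context.CHH and s.strand is Strand.PLUS]
        assert len(chh) >= 100
        levels = np.array([s.level for s in chh])
        se = np.sqrt(0.3 * 0.7 / (16 * len(chh)))
        assert levels.mean() == pytest.approx(0.3, abs=3 * se)
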