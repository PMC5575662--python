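"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes (optionally) simulate, then filter -> allocate ->
assemble -> overlap -> srna-map -> classify -> meth, writing every stage
output into a run directory together with a summary JSON that records the
seed, a hash of the configuration and per-stage record counts.  Re-running
with an identical configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

from . import io
from .accounting import LibraryCounts, accounting_text, library_accounting
from .allocation import (
    allocate_reads,
    build_feature_index,
    feature_distribution,
    genomic_category_distribution,
    heatmap_matrix,
)
from .loci import (
    assemble_loci,
    extend_loci,
    map_srnas,
    overlap_fraction,
    random_interval_null,
)
from .methylation import (
    Context,
    clone_methylation_levels,
    compare_genotypes,
    enumerate_contexts,
)
from .model import PipelineConfig
from .reads import acceptance_filter, length_filter, orient_reads
from .simulate import (
    SimulationSpec,
    extract_sequences,
    generate_annotation,
    generate_genome,
    simulate_bisulphite_clones,
    simulate_expression_table,
    simulate_rip_reads,
    simulate_srnas,
)
from .targets import (
    candidate_genes,
    classify_targets,
    compare_feature_profiles,
    venn_counts,
)

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "config_hash"]


def config_hash(config: Mapping[str, Any]) -> str:
    """Stable hash of the run configuration (order-independent)."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _spec_from_config(config: Mapping[str, Any], seed: int) -> tuple[SimulationSpec, int]:
    sim_cfg = dict(config.get("simulate") or {})
    n_reads = int(sim_cfg.pop("n_reads", 20_000))
    n_planted_rep = int(sim_cfg.pop("n_planted_repressed", 4))
    n_planted_act = int(sim_cfg.pop("n_planted_activated", 6))
    planted_fc = float(sim_cfg.pop("planted_fc", 4.0))
    fields = {f.name for f in dataclasses.fields(SimulationSpec)}
    unknown = set(sim_cfg) - fields
    if unknown:
        raise ValueError(f"unknown simulate options: {sorted(unknown)}")
    spec = SimulationSpec(seed=seed, **sim_cfg)
    # planted gene ids are assigned after annotation (deterministic ids)
    spec._n_planted = (n_planted_rep, n_planted_act, planted_fc)  # type: ignore[attr-defined]
    return spec, n_reads


def run_pipeline(
    config: Mapping[str, Any], outdir: str | Path, seed: int | None = None
) -> dict[str, Any]:
    """Run all configured stages; returns (and writes) the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    thresholds = PipelineConfig(
        random_seed=seed, **dict(config.get("thresholds") or {})
    )
    inputs = dict(config.get("inputs") or {})
    summary: dict[str, Any] = {
        "seed": seed,
        "config_hash": config_hash({k: v for k, v in config.items() if k != "outdir"}),
        "stages": {},
    }

    # ------------------------------------------------------------- simulate
    simulate = config.get("simulate") is not None or not inputs
    if simulate:
        spec, n_reads = _spec_from_config(config, seed)
        genome = generate_genome(spec)
        annotation = generate_annotation(genome, spec)
        n_rep, n_act, planted_fc = getattr(spec, "_n_planted", (0, 0, 4.0))
        coding = [g.gene_id for g in annotation if g.gene_id.startswith("g")]
        planted_rep = {gid: planted_fc for gid in coding[:n_rep]}
        planted_act = {gid: planted_fc for gid in coding[n_rep : n_rep + n_act]}
        spec = dataclasses.replace(
            spec, planted_repressed=planted_rep, planted_activated=planted_act
        )
        reads = simulate_rip_reads(genome, annotation, spec, n_reads)
        expression = simulate_expression_table(annotation, spec)
        srnas = None  # generated after locus assembly, from real locus territory
        io.write_fasta(genome.sequences, outdir / "genome.fasta")
        io.write_annotation(annotation, outdir / "annotation.gff3")
        io.write_intervals(genome.repeats, outdir / "repeats.bed")
        io.write_intervals(genome.transposons, outdir / "transposons.bed")
        io.write_reads_tsv(reads, outdir / "reads.tsv")
        io.write_expression(expression, outdir / "expression.tsv")
        repeats, transposons = genome.repeats, genome.transposons
        sequences = genome.sequences
        chrom_lengths = genome.lengths
        nuclear = set(genome.nuclear_chromosomes)
        summary["stages"]["simulate"] = {
            "n_reads": len(reads),
            "n_genes": len(annotation),
            "planted_repressed": sorted(planted_rep),
            "planted_activated": sorted(planted_act),
        }
    else:
        spec = None
        for required in ("genome", "annotation", "reads"):
            if required not in inputs:
                raise FileNotFoundError(
                    f"stage 'filter' requires input {required!r} when simulation "
                    "is disabled"
                )
        sequences = io.read_fasta(inputs["genome"])
        annotation = io.read_annotation(inputs["annotation"])
        reads = io.read_reads_tsv(inputs["reads"])
        expression = (
            io.read_expression(inputs["expression"]) if "expression" in inputs else None
        )
        srnas = io.read_fasta(inputs["srnas"]) if "srnas" in inputs else None
        repeats = io.read_intervals(inputs["repeats"]) if "repeats" in inputs else []
        transposons = (
            io.read_intervals(inputs["transposons"]) if "transposons" in inputs else []
        )
        chrom_lengths = {name: len(s) for name, s in sequences.items()}
        nuclear = {c for c in chrom_lengths if c not in ("ChrC", "ChrM")}

    organelles = set(chrom_lengths) - nuclear

    # --------------------------------------------------------------- filter
    sized = length_filter(reads, thresholds.min_read_len)
    accepted = acceptance_filter(
        sized,
        thresholds.min_identity,
        thresholds.min_aligned_fraction,
        thresholds.max_hits,
    )
    oriented = orient_reads(accepted)
    io.write_reads_tsv(oriented, outdir / "reads.filtered.tsv")
    nuclear_reads = [r for r in oriented if r.placement.chrom in nuclear]
    organellar_reads = [r for r in oriented if r.placement.chrom in organelles]
    summary["stages"]["filter"] = {
        "input_reads": len(reads),
        "after_length_filter": len(sized),
        "after_acceptance_filter": len(accepted),
    }
    table = library_accounting(
        {
            "library": LibraryCounts(
                total_reads=len(reads),
                nuclear_mapped=len(nuclear_reads),
                organellar_mapped=len(organellar_reads),
            )
        }
    )
    summary["read_accounting"] = json.loads(table.to_json(orient="index"))
    (outdir / "accounting.txt").write_text(accounting_text(table) + "\n")

    # ------------------------------------------------------------- allocate
    index = build_feature_index(
        annotation, flank=thresholds.flank, chrom_lengths=chrom_lengths
    )
    vectors, unassigned = allocate_reads(nuclear_reads, index)
    io.write_count_table(vectors, outdir / "gene_counts.tsv")
    categories = genomic_category_distribution(
        nuclear_reads, annotation, repeats, transposons
    )
    dist = feature_distribution(vectors)
    matrix = heatmap_matrix(vectors, min_total=thresholds.min_gene_reads)
    matrix.to_csv(outdir / "heatmap_matrix.tsv", sep="\t")
    summary["stages"]["allocate"] = {
        "allocated_reads": sum(v.total for v in vectors),
        "unassigned_reads": unassigned,
        "genes_with_reads": len(vectors),
        "category_fractions": categories.fractions,
        "repeat_associated_fraction": categories.repeat_associated,
        "feature_pct": {cls.value: pct for cls, pct in dist.items()},
    }

    # ------------------------------------------------------------- assemble
    loci = assemble_loci(nuclear_reads, max_gap=50, min_reads=2)
    extended = extend_loci(loci, thresholds.locus_extension, chrom_lengths)
    io.write_intervals(
        [l.interval for l in loci],
        outdir / "loci.bed",
        names=[f"locus{i:05d}" for i in range(len(loci))],
        scores=[l.n_reads for l in loci],
    )
    summary["stages"]["assemble"] = {"n_loci": len(loci)}

    # -------------------------------------------------------------- overlap
    if transposons and loci:
        nuclear_lengths = {c: chrom_lengths[c] for c in nuclear}
        observed = overlap_fraction([l.interval for l in loci], transposons)
        observed_ext = overlap_fraction([l.interval for l in extended], transposons)
        null = random_interval_null(
            [len(l.interval) for l in loci],
            nuclear_lengths,
            transposons,
            n_reps=int(config.get("overlap_n_reps", 200)),
            seed=seed,
            observed=observed,
        )
        overlap_summary = {
            "te_overlap_fraction": observed,
            "te_overlap_fraction_extended": observed_ext,
            "null_mean": float(null.null_fractions.mean()),
            "null_sd": float(null.null_fractions.std()),
            "empirical_p": null.empirical_p,
        }
        (outdir / "overlap.json").write_text(
            json.dumps(overlap_summary, indent=2, sort_keys=True)
        )
        summary["stages"]["overlap"] = overlap_summary
    else:
        summary["stages"]["overlap"] = "skipped: no transposon intervals or no loci"

    # ------------------------------------------------------------- srna-map
    if simulate and loci:
        # sample sRNAs from ~60 % of assembled loci so the mapped fraction
        # reflects a partially shared sRNA/lncRNA origin, as in AGO4 pull-downs
        rng_sel = spec.rng(7)
        k = max(1, int(0.6 * len(loci)))
        chosen = rng_sel.choice(len(loci), size=k, replace=False)
        source = [loci[i].interval for i in chosen if len(loci[i].interval) >= spec.srna_length]
        srnas = simulate_srnas(sequences, source, spec) if source else None
        if srnas:
            io.write_fasta(srnas, outdir / "srnas.fasta")
    if srnas and loci:
        loci_seqs = extract_sequences(sequences, [l.interval for l in extended])
        frac, hits = map_srnas(srnas, loci_seqs, thresholds.max_srna_mismatch)
        summary["stages"]["srna_map"] = {
            "n_srnas": len(srnas),
            "fraction_loci_with_srna": frac,
        }
    else:
        summary["stages"]["srna_map"] = "skipped: no sRNA sequences"

    # ------------------------------------------------------------- classify
    if expression is not None:
        candidates = candidate_genes(vectors, thresholds.min_gene_reads)
        targets = classify_targets(candidates, expression, thresholds.fc_threshold)
        up = {
            mutant: set(
                expression.index[expression[mutant] >= thresholds.fc_threshold]
            )
            for mutant in expression.columns
        }
        venn = venn_counts(targets.candidates, up)
        for name, genes_set in (
            ("candidates", targets.candidates),
            ("repressed", targets.repressed),
            ("activated", targets.activated),
        ):
            (outdir / f"genes_{name}.txt").write_text(
                "\n".join(sorted(genes_set)) + ("\n" if genes_set else "")
            )
        (outdir / "venn.json").write_text(json.dumps(venn, indent=2, sort_keys=True))
        summary["stages"]["classify"] = {
            "n_candidates": len(targets.candidates),
            "n_repressed": len(targets.repressed),
            "n_activated": len(targets.activated),
        }
        if targets.repressed and targets.activated:
            profiles = compare_feature_profiles(
                vectors, targets.repressed, targets.activated
            )
            profiles.to_csv(outdir / "feature_profiles.tsv", sep="\t")
    else:
        log.info("classification stage skipped: no expression table")
        summary["stages"]["classify"] = "skipped: no expression table"

    # ----------------------------------------------------------------- meth
    if simulate:
        region = next(
            (
                sequences[l.interval.chrom][l.interval.start : l.interval.end]
                for l in loci
                if 150 <= len(l.interval) <= 2000
            ),
            None,
        )
        if region is None and loci:
            iv = loci[0].interval
            region = sequences[iv.chrom][iv.start : iv.start + 500]
        if region:
            wt_clones = simulate_bisulphite_clones(region, spec)
            mut_spec = dataclasses.replace(spec, seed=spec.seed + 1)
            mut_clones = simulate_bisulphite_clones(
                region, mut_spec, meth_prob=spec.mutant_clone_meth_prob
            )
            sites = enumerate_contexts(region)
            wt = clone_methylation_levels(
                sites, [(s, st) for _, s, st in wt_clones], len(region)
            )
            mut = clone_methylation_levels(
                sites, [(s, st) for _, s, st in mut_clones], len(region)
            )
            comparison = compare_genotypes(wt, mut, min_delta=0.1)
            meth_summary = {
                ctx.value: {
                    "hypo": comparison.hypo.get(ctx, 0),
                    "hyper": comparison.hyper.get(ctx, 0),
                    "unchanged": comparison.unchanged.get(ctx, 0),
                }
                for ctx in (Context.CG, Context.CHG, Context.CHH)
            }
            (outdir / "methylation.json").write_text(
                json.dumps(meth_summary, indent=2, sort_keys=True)
            )
            summary["stages"]["meth"] = meth_summary
        else:
            summary["stages"]["meth"] = "skipped: no suitable region"
    else:
        summary["stages"]["meth"] = "skipped: clone analysis runs via the meth command"

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
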