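"""End-to-end orchestration: simulate -> quantify -> differential ->
taxonomy -> cis features -> RBP enrichment -> QC.

``run_pipeline`` takes a config mapping (or YAML path), executes every
stage, writes all tabular outputs as TSV plus a JSON run manifest
recording the seed and every threshold actually used.  In real-data
mode (config key ``inputs``) the simulation stage is skipped and
junction counts / expression / design / intron BED are loaded from the
given paths.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .annotation import introns_to_bed, read_introns_bed
from .diff import (
    ScanThresholds,
    differential_ir_scan,
    significant_union,
    splicing_event_census,
    splicing_factor_shift,
)
from .features import (
    ConservationTrack,
    background_intron_set,
    compare_categories,
    compute_cis_features,
    expression_coupling,
)
from .model import GenomicInterval, IntronRecord
from .qc import fractionation_leakage, sample_clustering, svd_structure
from .quant import compute_expression, compute_irt_fraction, compute_pir
from .rbp import build_enrichment_matrix, rank_rbps_by_category
from .simulate import (
    SimulationConfig,
    plan_truth,
    simulate_annotation_and_genome,
    simulate_conservation_track,
    simulate_crosslink_tracks,
    simulate_fraction_counts,
    truth_introns_as_records,
    write_bedgraph,
    write_crosslink_beds,
)
from .taxonomy import category_counts, classify_compartment

logger = logging.getLogger(__name__)


def load_config(config: Mapping | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as handle:
            return yaml.safe_load(handle) or {}
    return dict(config)


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> str:
    df.to_csv(path, sep="\t", index=index)
    return path.name


def run_pipeline(
    config: Mapping | str | Path,
    outdir: str | Path,
    seed: int | None = None,
    write_genome: bool = True,
) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    manifest: dict = {
        "fracir_version": __version__,
        "seed": seed,
        "outputs": {},
    }
    outputs = manifest["outputs"]

    sim_cfg = SimulationConfig.from_dict(cfg.get("simulation", {}))
    sim_cfg.seed = seed
    thresholds = ScanThresholds(**cfg.get("thresholds", {}))
    pir_opts = dict(cfg.get("pir", {}))
    min_junction_reads = int(pir_opts.get("min_junction_reads", 10))
    rbp_opts = dict(cfg.get("rbp", {}))
    manifest["thresholds"] = vars(thresholds).copy()
    manifest["pir"] = {"min_junction_reads": min_junction_reads}
    manifest["rbp"] = {
        "pseudocount": rbp_opts.get("pseudocount", 0.1),
        "background_stat": rbp_opts.get("background_stat", "median"),
    }

    inputs = cfg.get("inputs")
    genome = None
    conservation = None
    tracks = {}
    truth = None
    if inputs:
        logger.info("real-data mode: loading inputs, simulation skipped")
        counts = pd.read_csv(inputs["counts"], sep="\t")
        design = pd.read_csv(inputs["design"], sep="\t")
        expression_raw = pd.read_csv(inputs["expression"], sep="\t", index_col=0)
        introns = read_introns_bed(inputs["introns_bed"])
        housekeeping = list(cfg.get("housekeeping_genes", []))
        splicing_factors = list(cfg.get("splicing_factor_genes", []))
        if "conservation" in inputs:
            conservation = ConservationTrack.from_bedgraph(inputs["conservation"])
        if "crosslink_beds" in inputs:
            from .rbp import read_crosslink_beds
            tracks = read_crosslink_beds(inputs["crosslink_beds"])
    else:
        logger.info("simulation stage (seed=%d)", seed)
        manifest["simulation"] = sim_cfg.to_dict()
        if write_genome:
            gtf, fasta, truth = simulate_annotation_and_genome(sim_cfg, outdir, seed)
            outputs["annotation_gtf"] = gtf.name
            outputs["genome_fasta"] = fasta.name
            from .annotation import GenomeSequence
            genome = GenomeSequence(fasta)
        else:
            truth = plan_truth(sim_cfg, seed)
        truth.write(outdir)
        outputs["truth_introns"] = "truth_introns.tsv"
        counts, expression_raw, design = simulate_fraction_counts(
            sim_cfg, truth, seed
        )
        introns = truth_introns_as_records(truth)
        housekeeping = truth.housekeeping_genes
        splicing_factors = truth.splicing_factors
        tracks = simulate_crosslink_tracks(sim_cfg, truth, seed)
        bed_dir = outdir / "crosslinks"
        write_crosslink_beds(tracks, bed_dir)
        outputs["crosslink_bed_dir"] = "crosslinks"
        cons_track = simulate_conservation_track(sim_cfg, truth, seed)
        write_bedgraph(cons_track, outdir / "conservation.bedgraph")
        outputs["conservation_bedgraph"] = "conservation.bedgraph"
        conservation = ConservationTrack(cons_track)

    introns_by_id = {r.intron_id: r for r in introns}
    introns_to_bed(introns, outdir / "introns.bed")
    outputs["introns_bed"] = "introns.bed"
    outputs["counts"] = _write(counts, outdir / "counts.tsv")
    outputs["design"] = _write(design, outdir / "design.tsv")
    outputs["expression_raw"] = _write(
        expression_raw, outdir / "expression_raw.tsv", index=True
    )

    # quantification
    pir, coverage = compute_pir(counts, min_junction_reads=min_junction_reads)
    expr = compute_expression(expression_raw)
    outputs["pir"] = _write(pir, outdir / "pir.tsv", index=True)
    outputs["expression_log2"] = _write(
        expr.log2, outdir / "expression_log2.tsv", index=True
    )

    # differential scan + census + splicing-factor shift
    results = differential_ir_scan(pir, counts, design, thresholds)
    outputs["diff_results"] = _write(results, outdir / "diff_results.tsv")
    union = significant_union(results)
    outputs["significant_union"] = _write(union, outdir / "significant_union.tsv")
    census = splicing_event_census(results)
    outputs["census"] = _write(census, outdir / "census.tsv")
    if splicing_factors:
        shift = splicing_factor_shift(expr, splicing_factors, design)
        outputs["splicing_factor_shift"] = _write(
            shift, outdir / "splicing_factor_shift.tsv"
        )

    # taxonomy
    calls = classify_compartment(
        results, timepoint=cfg.get("taxonomy_timepoint")
    )
    outputs["taxonomy"] = _write(calls, outdir / "taxonomy.tsv")
    manifest["taxonomy_counts"] = category_counts(calls)
    manifest["taxonomy_timepoint"] = (
        int(calls["timepoint"].iloc[0]) if len(calls) else None
    )

    # cytoplasmic IRT share over classified introns
    if len(calls):
        irt = compute_irt_fraction(
            counts, calls["intron_id"].tolist(), design,
            fraction="cytoplasmic", timepoint=manifest["taxonomy_timepoint"],
        )
        outputs["irt_share"] = _write(irt, outdir / "irt_share.tsv")

    # cis features and comparisons
    feats = compute_cis_features(introns, genome=genome, conservation=conservation)
    outputs["features"] = _write(feats, outdir / "features.tsv")
    if len(calls):
        bg_records = background_intron_set(calls, introns)
        bg_feats = compute_cis_features(
            bg_records, genome=genome, conservation=conservation
        )
        comparisons = compare_categories(feats, calls, background=bg_feats)
        outputs["feature_comparisons"] = _write(
            comparisons, outdir / "feature_comparisons.tsv"
        )
        coupling = expression_coupling(expr, calls, design)
        outputs["expression_coupling"] = _write(
            coupling, outdir / "expression_coupling.tsv"
        )
        # RBP enrichment
        if tracks:
            call_records = [
                introns_by_id[i] for i in calls["intron_id"]
                if i in introns_by_id
            ]
            matrix = build_enrichment_matrix(
                tracks, call_records, bg_records,
                pseudocount=manifest["rbp"]["pseudocount"],
                background_stat=manifest["rbp"]["background_stat"],
            )
            outputs["enrichment_matrix"] = _write(
                matrix, outdir / "enrichment_matrix.tsv", index=True
            )
            try:
                ranking = rank_rbps_by_category(matrix, calls)
                outputs["rbp_ranking"] = _write(
                    ranking, outdir / "rbp_ranking.tsv"
                )
                manifest["n_enriched_rbps"] = int(ranking["enriched"].sum())
            except ValueError as exc:
                logger.warning("RBP ranking skipped: %s", exc)

    # QC
    if housekeeping:
        exonic_len = None
        if truth is not None:
            exonic_len = dict(
                zip(truth.genes["gene_id"], truth.genes["exonic_length"])
            )
        leak = fractionation_leakage(
            counts, introns, housekeeping, design, exonic_length=exonic_len
        )
        outputs["leakage"] = _write(leak, outdir / "leakage.tsv")
    variance, coords = svd_structure(expr.log2, design)
    outputs["svd_variance"] = _write(variance, outdir / "svd_variance.tsv")
    outputs["svd_coordinates"] = _write(coords, outdir / "svd_coordinates.tsv")
    manifest["svd_variance_fractions"] = [
        float(v) for v in variance["variance_fraction"].head(2)
    ]
    dist, newick = sample_clustering(expr.log2)
    outputs["clustering_distances"] = _write(
        dist, outdir / "clustering_distances.tsv", index=True
    )
    (outdir / "clustering.nwk").write_text(newick + "\n")
    outputs["clustering_newick"] = "clustering.nwk"

    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest
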