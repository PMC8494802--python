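"""End-to-end orchestration: simulate or load inputs, run every stage,
write tables and a manifest.  Re-running with the same configuration
reproduces byte-identical outputs."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__, io
from .config import PipelineConfig
from .depth import (
    aggregate_bins,
    correct_replication_timing,
    normalize_depth,
    qc_all,
    rebin,
)
from .genome import GenomeModel, toy_genome
from .haplotype import (
    attach_haplotype_means,
    bin_vaf,
    compute_haplotype_cn,
    detect_half_copy_segments,
    estimate_ploidy,
    flag_ploidy_outliers,
)
from .karyotype import TargetSite, classify_embryo, events_table
from .segment import CBSParams, segment_cn
from .simulate import CoverageModel, EventSpec, simulate_embryo, simulate_repliseq_track
from .snp import filter_informative_snps, informative_sites
from .sv import genotype_pipeline


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages and write the result bundle under ``outdir``.

    Returns a dict with the in-memory results (qc, segments, hap_segments,
    events, svs, manifest).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "embryocn",
        "version": __version__,
        "seed": config.seed,
        "parameters": json.loads(config.model_dump_json()),
        "stages": [],
    }
    results: dict = {"manifest": manifest}

    def stage(name):
        manifest["stages"].append(name)
        _write_manifest(manifest, outdir)
        return name

    try:
        stage("inputs")
        genome, counts, depths, svs, track, truth = _obtain_inputs(config)
        if truth is not None:
            io.write_ground_truth(truth, outdir / "ground_truth.yaml")
            io.write_bin_counts(counts, outdir / "bin_counts.tsv")
            io.write_allelic_depths(depths, outdir / "allelic_depths.tsv")
            io.write_repliseq(track, outdir / "repliseq.tsv")
    except Exception as e:  # noqa: BLE001
        raise StageError("inputs", e) from e

    try:
        stage("depth_cn")
        working = rebin(counts, config.effective_working_bin_size)
        norm = normalize_depth(
            working, config.low_coverage_fraction, config.low_coverage_sample_fraction
        )
        agg = aggregate_bins(norm, config.analysis_bin_size)
        if track is not None:
            agg = correct_replication_timing(agg, track, span=config.loess_span)
        qc = qc_all(agg, config.platform, thresholds=config.mad_thresholds)
        segments = segment_cn(
            agg, CBSParams(alpha=config.cbs_alpha, method=config.cbs_method)
        )
        io.write_table(qc, outdir / "qc.tsv")
        results.update(qc=qc, segments=segments, norm=agg)
    except Exception as e:  # noqa: BLE001
        raise StageError("depth_cn", e) from e

    try:
        stage("haplotype_cn")
        panel = filter_informative_snps(
            depths, config.vaf_window[0], config.vaf_window[1],
            config.min_covered_samples,
        )
        if config.panel_source == "cohort" and len(genome.snp_panel):
            sites = genome.snp_panel[["chrom", "pos"]].reset_index(drop=True)
        else:
            sites = informative_sites(panel)
        vaf_track = bin_vaf(depths, sites, agg.bins)
        calls = {s: estimate_ploidy(vaf_track, s) for s in agg.samples}
        flag_ploidy_outliers(list(calls.values()))
        hap = compute_haplotype_cn(vaf_track, agg, calls)
        # rescale depth-derived segment means to absolute CN for consistency
        seg_abs = segments.copy()
        factors = {s: 2.0 * calls[s].factor for s in calls}
        seg_abs["mean_cn"] = [
            m * factors.get(s, 2.0) for s, m in zip(seg_abs["sample"], seg_abs["mean_cn"])
        ]
        hap_segments = attach_haplotype_means(seg_abs, hap)
        hap_segments = detect_half_copy_segments(
            hap_segments, tolerance=config.half_copy_tolerance
        )
        io.write_table(panel, outdir / "snp_panel.tsv")
        io.write_table(hap, outdir / "haplotype_cn.tsv")
        io.write_table(hap_segments, outdir / "segments.tsv")
        ploidy_df = pd.DataFrame([asdict(c) for c in calls.values()])
        io.write_table(ploidy_df, outdir / "ploidy.tsv")
        results.update(panel=panel, hap=hap, hap_segments=hap_segments, ploidy=calls)
    except Exception as e:  # noqa: BLE001
        raise StageError("haplotype_cn", e) from e

    try:
        stage("sv_genotyping")
        if svs is not None and len(svs):
            embryo_map = {
                s: s.split(".", 1)[0] for s in
                (c.split(":", 1)[1] for c in svs.columns if c.startswith("split:"))
            }
            de_novo = genotype_pipeline(
                svs, embryo_map, config.sv_min_support, config.sv_min_mapq,
                config.sv_min_span, config.sv_presence_threshold,
            )
        else:
            de_novo = pd.DataFrame(
                columns=["id", "embryo", "n_blastomeres", "blastomeres"]
            )
        io.write_table(de_novo, outdir / "sv_de_novo.tsv")
        results["svs"] = de_novo
    except Exception as e:  # noqa: BLE001
        raise StageError("sv_genotyping", e) from e

    try:
        stage("karyotype_events")
        site = None
        if config.target_site is not None:
            site = TargetSite(
                config.target_site.name, config.target_site.chromosome,
                config.target_site.cut_position, config.target_site.tolerance,
            )
        consistent = [s for s, c in calls.items() if c.embryo_consistent]
        usable = hap_segments[hap_segments["sample"].isin(consistent)]
        events = classify_embryo(
            usable, genome, site, embryo=config.embryo,
            ploidy_calls={s: calls[s].call for s in consistent},
        )
        ev = events_table(events)
        io.write_table(ev, outdir / "events.tsv")
        results["events"] = events
        results["events_table"] = ev
    except Exception as e:  # noqa: BLE001
        raise StageError("karyotype_events", e) from e

    manifest["stages"].append("done")
    _write_manifest(manifest, outdir)
    return results


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _obtain_inputs(config: PipelineConfig):
    if config.simulate is not None:
        sim = config.simulate
        genome = toy_genome(
            n_chromosomes=sim.genome.n_chromosomes,
            chrom_lengths=tuple(sim.genome.chrom_lengths) if sim.genome.chrom_lengths else None,
            snp_spacing=sim.genome.snp_spacing,
            n_hom_sites=sim.genome.n_hom_sites,
            seed=sim.genome.seed,
        )
        track = simulate_repliseq_track(genome, config.native_bin_size, seed=config.seed)
        coverage = CoverageModel(
            mean_depth=sim.coverage.mean_depth,
            dispersion=sim.coverage.dispersion,
            repli_bias_strength=sim.coverage.repli_bias_strength,
            read_length=sim.coverage.read_length,
            seed=config.seed,
        )
        events = [EventSpec(**e.model_dump()) for e in sim.events]
        truth, counts, depths, svs = simulate_embryo(
            genome, events, coverage, phase=sim.phase, track=track,
            bin_size=config.native_bin_size, with_svs=sim.with_svs,
        )
        svs = svs if sim.with_svs else None
        return genome, counts, depths, svs, track, truth
    if config.inputs is None or config.inputs.counts is None:
        raise ValueError("config must provide either a simulate block or input paths")
    counts = io.read_bin_counts(config.inputs.counts)
    depths = io.read_allelic_depths(config.inputs.allelic_depths)
    track = io.read_repliseq(config.inputs.repliseq) if config.inputs.repliseq else None
    svs = io.read_table(config.inputs.svs) if config.inputs.svs else None
    chroms = tuple(
        (c, int(g["end"].max()))
        for c, g in counts.bins.groupby("chrom", sort=False)
    )
    panel = depths[["chrom", "pos", "ref", "alt"]].drop_duplicates().reset_index(drop=True)
    genome = GenomeModel(chromosomes=chroms, snp_panel=panel)
    return genome, counts, depths, svs, track, None
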