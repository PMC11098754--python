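"""End-to-end orchestration of a synthetic lineage-tracing run.

``run_pipeline`` wires the stages in fixed order — simulate clonal growth,
generate barcoded reads, quantify, filter, summarize, compare — writing
every intermediate table and a manifest to an output directory.  All
randomness flows from the single config seed; two runs of the same config
produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as ctio
from . import model, pipeline, stats, synth, transport
from .io import RunConfig

log = logging.getLogger("clonetrace")


def _kv(stage: str, **kwargs) -> None:
    log.info("stage=%s %s", stage, " ".join(f"{k}={v}" for k, v in kwargs.items()))


def build_scenario(config: RunConfig):
    """Simulate organoids and sequence them into one read pool.

    Whole-organoid sampling is destructive, so every (timepoint, replicate)
    combination is an independent organoid with its own block of library
    barcodes, named ``d<time>_r<replicate>``.  Returns (sample sheet, reads,
    truth table, library).
    """
    sim_cfg, gen_cfg = config.simulate, config.generate
    n_organoids = len(sim_cfg.record_times) * gen_cfg.replicates
    ss = np.random.SeedSequence(config.seed)
    lib_seed, sheet_seed, read_seed, *org_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3 + n_organoids)
    ]
    library = synth.generate_barcode_library(
        n=gen_cfg.n_barcodes,
        library_id="lib1",
        identifier=gen_cfg.identifier,
        length=gen_cfg.barcode_length,
        seed=lib_seed,
    )
    if gen_cfg.n_barcodes < sim_cfg.n_lineages * n_organoids:
        raise ValueError("n_barcodes must cover n_lineages x timepoints x replicates")
    samples, timepoints, replicates = [], [], []
    sample_clones: dict[str, pd.DataFrame] = {}
    truth_frames = []
    organoid = 0
    for r in range(1, gen_cfg.replicates + 1):
        for t in sim_cfg.record_times:
            params = model.ModelParameters(
                r_s=sim_cfg.r_s,
                r_a=sim_cfg.r_a,
                r_n=sim_cfg.r_n,
                r_dn=sim_cfg.r_dn,
                k=sim_cfg.k,
                variant=sim_cfg.variant,
                t_end=t,
                n_lineages=sim_cfg.n_lineages,
                record_times=(t,),
                seed=org_seeds[organoid],
            )
            sim = model.simulate_organoid(params)
            offset = organoid * sim_cfg.n_lineages
            sub_lib = synth.BarcodeLibrary(
                library_id=library.library_id,
                identifier=library.identifier,
                identifier_pos=library.identifier_pos,
                length=library.length,
                barcodes=library.barcodes[offset : offset + sim_cfg.n_lineages],
            )
            clones = synth.clones_from_simulation(sim, sub_lib)
            clones["replicate"] = r
            truth_frames.append(clones)
            name = f"d{t:g}_r{r}"
            samples.append(name)
            timepoints.append(t)
            replicates.append(r)
            sample_clones[name] = clones
            organoid += 1
    sheet = synth.make_sample_sheet(
        samples,
        seed=sheet_seed,
        timepoints=timepoints,
        replicates=replicates,
        library_ids=[library.library_id] * len(samples),
    )
    reads = synth.generate_reads(
        clones=None,
        sample_sheet=sheet,
        sample_clones=sample_clones,
        depth=gen_cfg.depth,
        substitution_rate=gen_cfg.substitution_rate,
        cross_sample_rate=gen_cfg.cross_sample_rate,
        seed=read_seed,
    )
    truth = pd.concat(truth_frames, ignore_index=True)
    return sheet, reads, truth, library


def run_pipeline(config: RunConfig, out_dir: str | Path, write_fastq: bool = False) -> dict:
    """Execute generate -> count -> filter -> stats -> compare; write artifacts.

    Returns the stage tallies and output paths.  A structured key=value log
    line records the input/output row counts of every stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sheet, reads, truth, library = build_scenario(config)
    ctio.write_sample_sheet(sheet, out / "sample_sheet.tsv")
    truth.to_csv(out / "truth_clones.tsv", sep="\t", index=False)
    _kv("generate", samples=len(sheet), reads=len(reads), lineages=config.simulate.n_lineages)
    if write_fastq:
        ctio.write_readset(reads, out / "reads")
    table, dists, tally = pipeline.run_quantification(
        reads,
        sheet,
        barcode_length=config.count.barcode_length,
        max_index_distance=config.count.max_index_distance,
        cluster_max_distance=config.count.cluster_max_distance,
        cluster_ratio=config.count.cluster_ratio,
        cross_sample_factor=config.filter.cross_sample_factor,
        threshold_floor=config.filter.threshold_floor,
        threshold_method=config.filter.threshold_method,
        library_size=len(library.barcodes),
        outlier_alpha=config.filter.outlier_alpha,
    )
    _kv("quantify", **tally)
    ctio.write_counts_tsv(table, out / "counts.tsv")
    ctio.write_rpm_tsv(dists, out / "rpm.tsv")

    # per-sample summary statistics
    rows = []
    for name, dist in sorted(dists.items()):
        summary = stats.divergence_summary(dist)
        summary.update(
            sample=name,
            n_lineages=len(dist),
            top_share=stats.top_percentile_share(dist, config.stats.top_percent),
            size_orders=stats.size_range_orders(dist),
        )
        rows.append(summary)
    stat_df = pd.DataFrame(rows)
    stat_df.to_csv(out / "stats.tsv", sep="\t", index=False)
    _kv("stats", samples=len(stat_df))

    # lineage counts over time with replicate s.e.m.
    by_time: dict[float, list] = {}
    for name, dist in dists.items():
        t = float(sheet.loc[sheet["sample"] == name, "timepoint"].iloc[0])
        by_time.setdefault(t, []).append(dist)
    counts_df = stats.lineage_count_over_time(by_time)
    counts_df.to_csv(out / "lineage_counts.tsv", sep="\t", index=False)

    # transport between consecutive timepoints within each replicate,
    # averaged over replicates
    times = sorted(by_time)
    curve_rows = []
    for t0, t1 in zip(times, times[1:]):
        results = []
        for r in range(1, config.generate.replicates + 1):
            a, b = f"d{t0:g}_r{r}", f"d{t1:g}_r{r}"
            if a in dists and b in dists:
                xa, xb = transport.harmonize_thresholds(dists[a], dists[b])
                results.append(transport.rank_transport(xa, xb))
        if not results:
            continue
        curve = transport.fold_change_curve(
            results,
            lowess_frac=config.compare.lowess_frac,
            trim_top=config.compare.trim_top,
        )
        curve_rows.append(
            pd.DataFrame(
                {
                    "from_time": t0,
                    "to_time": t1,
                    "source_rpm": curve.grid,
                    "log2fc": curve.log2fc,
                    "density": curve.density,
                }
            )
        )
        _kv("compare", pair=f"d{t0:g}->d{t1:g}", replicates=len(results))
    if curve_rows:
        pd.concat(curve_rows, ignore_index=True).to_csv(
            out / "fold_change_curves.tsv", sep="\t", index=False
        )
    ctio.write_manifest(
        out / "manifest.json",
        {"seed": config.seed, "config": config.model_dump(), "tally": tally},
    )
    return {"tally": tally, "out_dir": str(out)}
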