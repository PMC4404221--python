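"""End-to-end orchestration: simulate -> demux/count -> call -> report.

Every run writes a machine-readable manifest recording stage-level read and
sample counts, so conservation (reads in = reads routed; samples in =
called + missing) can be audited after the fact.  All outputs are plain
text (TSV / VCF / JSON) and byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import calling, demux, simulate
from .config import RunConfig
from .errors import PipelineError
from .io import read_fastq
from .markers import (
    BarcodeSet,
    generate_barcode_set,
    load_barcodes_tsv,
    load_markers_tsv,
    write_barcodes_tsv,
)

log = logging.getLogger("spikegbs")


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and write all artifacts under ``outdir``.

    Returns the run manifest (also written to ``manifest.json``).  Raises a
    spikegbs error if any stage fails; partial outputs written before the
    failure are noted in the exception message where possible.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}}

    markers = load_markers_tsv(config.markers_tsv)
    log.info("loaded %d markers from %s", len(markers), config.markers_tsv)

    if config.barcodes_tsv is not None:
        barcodes = load_barcodes_tsv(config.barcodes_tsv, parts=config.parts)
    elif config.simulate is not None:
        barcodes = generate_barcode_set(
            config.simulate.n_samples, length=10, min_hamming=3,
            seed=config.simulate.seed,
        )
        write_barcodes_tsv(barcodes, outdir / "barcodes.tsv")
    else:
        raise PipelineError("no barcode TSV given and not in simulate mode")

    gbs_barcodes: BarcodeSet | None = None

    # --- stage 1: obtain reads -------------------------------------------
    if config.fastq is not None:
        fastq_path = config.fastq
        truth = None
    else:
        sim = config.simulate
        result = simulate.simulate_run(
            sim, markers, barcodes=barcodes, parts=config.parts,
            n_reads=config.n_reads, fastq_path=outdir / "simulated.fastq",
        )
        fastq_path = result.fastq_path
        truth = result.truth
        gbs_barcodes = result.gbs_barcodes
        simulate.truth_to_tsv(truth, outdir / "truth.tsv")
        demux.counts_to_tsv(
            result.audit_counts.assign(count_unmatched=0), outdir / "audit_counts.tsv"
        )
        write_barcodes_tsv(gbs_barcodes, outdir / "gbs_barcodes.tsv")
        manifest["stages"]["simulate"] = {
            "n_amplicon": result.n_amplicon,
            "n_background": result.n_background,
            "n_total": result.n_amplicon + result.n_background,
        }
        log.info("simulated %d reads (%d amplicon, %d background)",
                 result.n_amplicon + result.n_background,
                 result.n_amplicon, result.n_background)

    # --- stage 2: demultiplex and count ----------------------------------
    cut_site = config.simulate.cut_site_remnant if config.simulate else None
    table, qc = demux.count_alleles(
        read_fastq(fastq_path), config.parts, barcodes, markers,
        gbs_barcodes=gbs_barcodes, cut_site_remnant=cut_site,
    )
    demux.counts_to_tsv(table, outdir / "allele_counts.tsv")
    with open(outdir / "run_qc.json", "w") as handle:
        json.dump(qc.as_dict(), handle, indent=2)
        handle.write("\n")
    routed = qc.amplicon_reads + qc.gbs_reads + qc.unassigned
    if routed != qc.total_reads:
        raise PipelineError(
            f"routing does not conserve reads: {routed} != {qc.total_reads}"
        )
    manifest["stages"]["count"] = qc.as_dict()
    if qc.total_reads == 0:
        log.warning("input FASTQ %s contained no reads", fastq_path)
    log.info("routed %d reads: %d amplicon / %d gbs / %d unassigned "
             "(spiked fraction %.4f)", qc.total_reads, qc.amplicon_reads,
             qc.gbs_reads, qc.unassigned, qc.spiked_fraction)

    # --- stage 3: genotype calling ---------------------------------------
    c = config.calling
    samples = barcodes.samples
    points = calling.depth_filter(table, min_depth=c.min_depth) if len(table) else None
    matrices: dict[str, pd.DataFrame] = {}
    for method in config.methods:
        gm = calling.call_genotypes(
            table, markers, method=method, min_depth=c.min_depth,
            k=c.k, eps=c.eps, eps_per_locus=c.eps_per_locus,
            min_pts=c.min_pts, seed=c.seed, samples=samples,
            on_labeling_error="flag",
        )
        matrices[method] = gm
        calling.genotype_matrix_to_tsv(gm, outdir / f"genotypes_{method}.tsv")
        calling.write_vcf(gm, markers, outdir / f"genotypes_{method}.vcf",
                          sample_order=samples)
        if points is not None:
            calling.scatter_to_tsv(points, gm, outdir / f"scatter_{method}.tsv")
        summary = calling.marker_summary(gm, table, min_depth=c.min_depth,
                                         n_samples=len(samples))
        calling.summary_to_tsv(summary, outdir / f"marker_summary_{method}.tsv")
        n_called = int((gm["label"] != calling.MISSING).sum())
        manifest["stages"][f"call_{method}"] = {
            "n_cells": len(gm),
            "n_called": n_called,
            "n_missing": len(gm) - n_called,
            "flagged_loci": gm.attrs.get("flagged_loci", []),
        }
        if gm.attrs.get("flagged_loci"):
            log.warning("%s: loci flagged for manual curation: %s",
                        method, gm.attrs["flagged_loci"])
        log.info("%s: called %d of %d cells", method, n_called, len(gm))

    # --- stage 4: concordance and truth cross-check ----------------------
    if len(matrices) == 2:
        overall, co, n_co = calling.concordance(
            matrices["kmeans"], matrices["dbscan"]
        )
        report = {
            "overall_agreement": overall,
            "co_classified_agreement": co,
            "n_co_classified": n_co,
        }
        with open(outdir / "concordance.json", "w") as handle:
            json.dump(report, handle, indent=2)
            handle.write("\n")
        manifest["stages"]["concordance"] = report
        log.info("method concordance: overall %.4f, co-classified %.4f (n=%d)",
                 overall, co, n_co)

    if truth is not None and matrices:
        recov = {
            method: genotype_recovery(gm, truth)
            for method, gm in matrices.items()
        }
        manifest["stages"]["truth_recovery"] = recov
        for method, r in recov.items():
            log.info("%s: %.2f%% of called cells match simulated truth",
                     method, 100 * r)

    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2)
        handle.write("\n")
    return manifest


def genotype_recovery(gm: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Fraction of non-MISSING calls equal to simulated truth (1.0 if none called)."""
    merged = gm.merge(
        truth[["sample_id", "locus_id", "true_class"]],
        on=["sample_id", "locus_id"], how="inner",
    )
    called = merged[merged["label"] != calling.MISSING]
    if called.empty:
        return 1.0
    return float((called["label"] == called["true_class"]).mean())
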