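"""End-to-end orchestration: profiles -> decontam -> enrichment ->
networks -> replication -> associations, with a machine-readable run
report.

Every stage writes its artefacts into the output directory and appends
its input/output dimensions to the report; the report JSON is
byte-identical across runs with identical inputs, config and seed
(timestamps are deliberately excluded).
"""

from __future__ import annotations

import json
import logging
import os

import pandas as pd

from . import __version__
from .errors import DataError
from . import profiles as prof
from . import decontam as dec
from . import annotate as ann
from . import cooccur as net
from . import replication as rep
from . import assoc as assoc_mod
from .config import PipelineConfig

log = logging.getLogger("bloodsift")


def _load_counts(config: PipelineConfig) -> pd.DataFrame:
    if config.counts_tsv:
        return prof.read_count_matrix_tsv(config.counts_tsv)
    if config.kraken_dir:
        profiles = prof.parse_kraken2_reports(config.kraken_dir)
        return prof.build_count_matrix(profiles)
    raise DataError("no count input: set counts_tsv or kraken_dir")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the run report dict."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {
        "tool": "bloodsift",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    # ---------------- profiles: QC + presence
    counts = _load_counts(config)
    if config.metadata_tsv is None:
        raise DataError("metadata_tsv is required")
    meta = prof.read_metadata_tsv(config.metadata_tsv)
    prof.check_metadata_covers(counts, meta)
    qcd = prof.qc_samples(counts, config.min_total_reads)
    removed = counts.index.difference(qcd.index)
    pd.DataFrame({
        "sample_id": removed,
        "reason": [f"total reads < {config.min_total_reads}"] * len(removed),
    }).to_csv(os.path.join(config.outdir, "qc_log.tsv"), sep="\t", index=False)
    if qcd.shape[0] == 0:
        raise DataError("no samples survive QC")
    presence = prof.call_presence(
        qcd, config.ra_threshold, config.count_threshold, config.presence_rule
    )
    detected = presence.species_detected()
    prof.write_count_matrix_tsv(
        presence.zeroed_counts, os.path.join(config.outdir, "counts_zeroed.tsv")
    )
    prof.write_presence_tsv(
        presence.present, os.path.join(config.outdir, "presence.tsv")
    )
    report["stages"]["profiles"] = {
        "n_samples_in": int(counts.shape[0]),
        "n_samples_qc": int(qcd.shape[0]),
        "n_species_in": int(counts.shape[1]),
        "n_species_detected": len(detected),
    }
    log.info("profiles: %d/%d samples pass QC, %d species detected",
             qcd.shape[0], counts.shape[0], len(detected))
    meta = meta.loc[qcd.index]

    # ---------------- decontamination
    survivors = detected
    if config.run_decontam:
        dconf = dec.DecontamConfig(
            variables=config.batch_variables,
            min_batch_size=config.min_batch_size,
            prev_threshold=config.prev_threshold,
            fold=config.prev_fold,
            rho_threshold=config.rho_threshold,
            excluded_variables=tuple(config.excluded_variables),
            min_max_reads=config.min_max_reads,
            zero_replacement_factor=config.zero_replacement_factor,
        )
        dreport = dec.run_decontamination(presence, meta, dconf)
        dreport.to_json(os.path.join(config.outdir, "decontam_report.json"))
        dreport.calls_table().to_csv(
            os.path.join(config.outdir, "contaminant_calls.tsv"),
            sep="\t", index=False,
        )
        survivors = dreport.survivors
        report["stages"]["decontam"] = {
            "species_before": dreport.species_before,
            "species_after_each_filter": dreport.species_after_each_filter,
            "n_calls": len(dreport.calls),
            "n_survivors": len(survivors),
        }
        log.info("decontam: %d -> %s species",
                 dreport.species_before, dreport.species_after_each_filter)

    summary = ann.species_summary(presence.present[survivors])
    prev = ann.prevalence_table(presence.present[survivors])
    prev.to_csv(os.path.join(config.outdir, "prevalence.tsv"), sep="\t",
                header=True)
    report["stages"]["summary"] = {
        "zero_species_fraction": summary.zero_fraction,
        "median_species_nonzero_samples": summary.median_nonzero,
        "top_prevalence": float(prev.max()) if len(prev) else None,
    }

    # ---------------- enrichment randomization
    if config.run_enrichment and config.annotation_tsv:
        db = ann.read_annotation_tsv(config.annotation_tsv)
        if not survivors:
            raise DataError("enrichment stage: no surviving species")
        results = ann.enrichment_suite(
            detected, survivors, db,
            n_iter=config.enrichment_iters, seed=config.seed,
        )
        ann.write_enrichment_json(
            results, os.path.join(config.outdir, "enrichment.json")
        )
        report["stages"]["enrichment"] = {
            cat: {"observed": r.observed_proportion, "p": r.p_value,
                  "direction": r.direction}
            for cat, r in results.items()
        }
        log.info("enrichment: %s",
                 {c: r.p_text() for c, r in results.items()})

    # ---------------- co-occurrence networks
    if config.run_networks:
        stage: dict = {}
        try:
            pooled_counts = presence.zeroed_counts[survivors]
            if config.pooled_excludes_cohorts and config.excluded_cohorts:
                keep = ~meta["cohort"].isin(config.excluded_cohorts)
                pooled_counts = pooled_counts.loc[keep.index[keep]]
            selected = net.select_network_samples(
                presence.present[survivors].loc[pooled_counts.index],
                pooled_counts,
            )
            corr = net.sparcc(
                selected,
                n_exclusion_iters=config.sparcc_exclusion_iters,
                exclusion_threshold=config.sparcc_exclusion_threshold,
                pseudocount=config.sparcc_pseudocount,
                n_draws=config.sparcc_draws,
                seed=config.seed,
            )
            net.write_correlation_tsv(
                corr, os.path.join(config.outdir, "sparcc_all.tsv")
            )
            stage["pooled"] = {"n_samples": int(selected.shape[0])}
            for t in config.network_thresholds:
                g = net.build_network(corr, t)
                net.write_edge_list(
                    g, os.path.join(config.outdir, f"network_all_t{t}.tsv")
                )
                net.write_graphml(
                    g, os.path.join(config.outdir, f"network_all_t{t}.graphml")
                )
                stage["pooled"][f"edges_t{t}"] = g.number_of_edges()
            cohort_graphs = []
            stage["cohorts"] = {}
            for cohort, sub_meta in meta.groupby("cohort", sort=True):
                if cohort in config.excluded_cohorts:
                    continue
                sub = presence.zeroed_counts.loc[sub_meta.index, survivors]
                try:
                    sel = net.select_network_samples(
                        presence.present.loc[sub_meta.index, survivors], sub
                    )
                    corr_c = net.sparcc(
                        sel,
                        n_exclusion_iters=config.sparcc_exclusion_iters,
                        exclusion_threshold=config.sparcc_exclusion_threshold,
                        pseudocount=config.sparcc_pseudocount,
                        n_draws=config.sparcc_draws,
                        seed=config.seed,
                    )
                except DataError as exc:
                    stage["cohorts"][str(cohort)] = {"skipped": str(exc)}
                    continue
                g = net.build_network(corr_c, config.cohort_network_threshold)
                cohort_graphs.append(g)
                net.write_edge_list(
                    g, os.path.join(config.outdir, f"network_{cohort}.tsv")
                )
                stage["cohorts"][str(cohort)] = {
                    "n_samples": int(sel.shape[0]),
                    "edges": g.number_of_edges(),
                }
            if len(cohort_graphs) >= 2:
                inter = net.intersect_networks(cohort_graphs)
                net.write_edge_list(
                    inter,
                    os.path.join(config.outdir, "network_intersection.tsv"),
                )
                stage["intersection_edges"] = inter.number_of_edges()
        except DataError as exc:
            stage["skipped"] = str(exc)
        report["stages"]["networks"] = stage

    # ---------------- replication
    if config.run_replication and config.coverage_inputs:
        results = []
        stage = {}
        for item in config.coverage_inputs:
            genome_id = item.get("genome_id", "")
            track = rep.read_depth_tsv(
                item["depth_tsv"], genome_id=genome_id,
                length=item.get("length"),
            )
            breadth = rep.coverage_breadth(track) if track.bin_size is None else None
            smoothed = rep.bin_and_smooth(
                track, config.bin_size, config.median_window_bins
            )
            res = rep.estimate_ptr(smoothed)
            res.coverage_breadth = breadth
            res = rep.call_replicating(
                res, int(item.get("assigned_reads", 0)),
                config.min_assigned_reads, config.ptr_threshold,
            )
            results.append(res)
            if item.get("fasta"):
                from Bio import SeqIO
                rec = next(SeqIO.parse(item["fasta"], "fasta"))
                skew = rep.gc_skew_ori_ter(
                    str(rec.seq), config.skew_window, genome_id=genome_id
                )
                stage.setdefault("gc_skew", {})[genome_id] = {
                    "ori": skew.ori_position, "ter": skew.ter_position,
                    "degenerate": skew.degenerate,
                }
        rep.write_ptr_json(
            results, os.path.join(config.outdir, "ptr_results.json")
        )
        stage["ptr_calls"] = {
            r.genome_id: {"ptr": r.ptr, "replicating": r.replicating}
            for r in results
        }
        report["stages"]["replication"] = stage

    # ---------------- associations
    if config.run_assoc and config.phenotype_tsv:
        pheno = pd.read_csv(config.phenotype_tsv, sep="\t", index_col=0)
        pheno.index = pheno.index.astype(str)
        measured, derived, skips = assoc_mod.run_association_screen(
            presence.present[survivors], pheno,
            min_present=config.min_present, alpha=config.alpha,
            seed=config.seed,
        )
        measured.to_csv(
            os.path.join(config.outdir, "associations_measured.tsv"),
            sep="\t", index=False,
        )
        derived.to_csv(
            os.path.join(config.outdir, "associations_derived.tsv"),
            sep="\t", index=False,
        )
        with open(os.path.join(config.outdir, "association_skips.json"), "w") as fh:
            json.dump(skips, fh, indent=2, sort_keys=True)
        report["stages"]["assoc"] = {
            "n_tests_measured": int(len(measured)),
            "n_tests_derived": int(len(derived)),
            "n_significant_measured": int(
                (measured["p_adjusted"] < config.alpha).sum()
            ) if len(measured) else 0,
            "n_significant_derived": int(
                (derived["p_adjusted"] < config.alpha).sum()
            ) if len(derived) else 0,
            "n_skipped": len(skips),
        }

    report_path = os.path.join(config.outdir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("report written to %s", report_path)
    return report
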