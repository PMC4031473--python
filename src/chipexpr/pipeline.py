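"""End-to-end orchestration: targets → co-occupancy → profiles → DE → activity → motifs.

``run_all`` drives every stage from one :class:`PipelineConfig` and a
dictionary of input paths, writes per-stage outputs under an output
directory, and returns a machine-readable :class:`RunReport` whose
statistics equal the values in the stage output files.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import activity, cooccupancy, diffexpr, io as gio, motifs, profiles, targets
from .config import PipelineConfig
from .core import ConfigurationError

log = logging.getLogger("chipexpr")

REQUIRED_INPUTS = ("peaks_a", "genes", "expression", "conditions")
OPTIONAL_INPUTS = ("peaks_b", "peaks_c", "coverage_a", "genome")


@dataclass
class RunReport:
    """Key statistics and output paths of one pipeline run."""

    config: Dict[str, object]
    inputs: Dict[str, str]
    outputs: Dict[str, str] = field(default_factory=dict)
    stats: Dict[str, object] = field(default_factory=dict)
    timestamps: Dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config": self.config, "inputs": self.inputs,
                 "outputs": self.outputs, "stats": self.stats,
                 "timestamps": self.timestamps},
                fh, indent=1, sort_keys=True, default=str,
            )

    def summary_lines(self) -> List[str]:
        lines = ["pipeline run summary", "===================="]
        for key in sorted(self.stats):
            lines.append(f"{key}: {self.stats[key]}")
        return lines


def run_all(config: PipelineConfig, inputs: Dict[str, str],
            outdir: str) -> RunReport:
    """Run every stage in dependency order; any stage failure names the stage.

    ``inputs`` keys: peaks_a (required, narrowPeak), peaks_b / peaks_c
    (optional partners), genes (refFlat), expression + conditions (TSV +
    YAML), coverage_a (bedGraph), genome (FASTA).  Numeric outputs are
    deterministic given the same inputs and config.
    """
    for key in REQUIRED_INPUTS:
        if key not in inputs:
            raise ConfigurationError(f"missing required input {key!r}")
    for key, path in inputs.items():
        if not os.path.exists(path):
            raise ConfigurationError(f"input {key!r} not found: {path}")
    os.makedirs(outdir, exist_ok=True)
    report = RunReport(config.to_dict(), dict(inputs))
    stage = "load"
    try:
        peaks_a = gio.read_peaks(inputs["peaks_a"], "narrowpeak")
        genes = gio.read_gene_annotation(inputs["genes"], "refflat")
        expr = gio.read_expression(inputs["expression"], inputs["conditions"])
        peaks_b = (gio.read_peaks(inputs["peaks_b"], "narrowpeak")
                   if "peaks_b" in inputs else None)
        peaks_c = (gio.read_peaks(inputs["peaks_c"], "narrowpeak")
                   if "peaks_c" in inputs else None)
        _log_stage(report, stage, peaks_a=len(peaks_a), genes=len(genes))

        stage = "filter"
        peaks_a_f = cooccupancy.filter_by_fold(peaks_a, config.fold_threshold)
        peaks_b_f = (cooccupancy.filter_by_fold(peaks_b, config.fold_threshold)
                     if peaks_b is not None else None)
        peaks_c_f = (cooccupancy.filter_by_fold(peaks_c, config.fold_threshold)
                     if peaks_c is not None else None)
        report.stats["n_peaks_a_filtered"] = len(peaks_a_f)
        _log_stage(report, stage, kept=len(peaks_a_f))

        stage = "targets"
        tmap_a = targets.assign_targets(peaks_a_f, genes, config.tss_window)
        expressed = targets.expressed_genes(
            expr, config.expression_threshold, {g.gene_id for g in genes}
        )
        expressed_targets = tmap_a.target_genes & expressed
        path = os.path.join(outdir, "targets_a.tsv")
        targets.write_target_map(tmap_a, peaks_a_f, path)
        report.outputs["targets_a"] = path
        feat = targets.classify_peak_locations(peaks_a_f, genes,
                                               config.tss_window)
        path = os.path.join(outdir, "feature_distribution_a.tsv")
        targets.write_feature_distribution(feat, path)
        report.outputs["feature_distribution_a"] = path
        report.stats["n_target_genes_a"] = len(tmap_a.target_genes)
        report.stats["n_expressed_genes"] = len(expressed)
        report.stats["n_expressed_target_genes_a"] = len(expressed_targets)
        report.stats["promoter_fraction_a"] = feat["promoter"][1]
        _log_stage(report, stage, targets=len(tmap_a.target_genes))

        stage = "cooccupancy"
        universe = {g.gene_id for g in genes}
        if peaks_b_f is not None:
            part = cooccupancy.partition_solo_ensemble(
                peaks_a_f, peaks_b_f, config.min_overlap_bp, "factor_b"
            )
            for kind, plist in (("ensemble", part.ensemble), ("solo", part.solo)):
                path = os.path.join(outdir, f"peaks_a_{kind}.narrowPeak")
                gio.write_peaks(plist, path)
                report.outputs[f"peaks_a_{kind}"] = path
            report.stats["n_ensemble_peaks"] = len(part.ensemble)
            report.stats["n_solo_peaks"] = len(part.solo)
            tmap_b = targets.assign_targets(peaks_b_f, genes, config.tss_window)
            overlap = cooccupancy.target_overlap_significance(
                tmap_a.target_genes, tmap_b.target_genes, universe
            )
            report.stats["target_overlap_k"] = overlap.overlap
            report.stats["target_overlap_p"] = overlap.p_value
            sets = {"factor_a": tmap_a.target_genes,
                    "factor_b": tmap_b.target_genes}
            if peaks_c_f is not None:
                tmap_c = targets.assign_targets(peaks_c_f, genes,
                                                config.tss_window)
                sets["factor_c"] = tmap_c.target_genes
            venn = cooccupancy.venn_counts(sets)
            report.stats["venn_counts"] = {
                "+".join(k): v for k, v in venn.items()
            }
            _log_stage(report, stage, ensemble=len(part.ensemble),
                       solo=len(part.solo))
        else:
            part = None

        stage = "profiles"
        if "coverage_a" in inputs:
            track = gio.read_coverage(inputs["coverage_a"], "bedgraph")
            by_id = {}
            for g in genes:
                by_id.setdefault(g.gene_id, g)
            anchor_genes = [by_id[gid] for gid in sorted(expressed_targets)
                            if gid in by_id]
            if anchor_genes:
                anchors = [(g.chrom, g.tss, g.strand) for g in anchor_genes]
                pm = profiles.profile_matrix(
                    track, anchors, config.heatmap_halfwindow,
                    config.profile_bins,
                    [g.gene_id for g in anchor_genes],
                )
                order = profiles.order_anchors_by_signal(
                    pm, max(1, 500 // pm.bin_width)
                )
                path = os.path.join(outdir, "tss_profile_a.tsv")
                profiles.write_profile_matrix(
                    pm, path, os.path.join(outdir, "tss_profile_a_bins.json")
                )
                report.outputs["tss_profile_a"] = path
                report.stats["tss_profile_mean_center"] = float(
                    profiles.average_profile(pm)[pm.nbins // 2]
                )
                # expression trend along the signal-ordered heatmap
                control = expr.columns_for("control").mean(axis=1)
                by_gene = dict(zip(expr.row_ids, control))
                series = [by_gene[g] for g in order if g in by_gene]
                if len(series) >= config.smooth_window:
                    smoothed = profiles.sliding_window_smooth(
                        series, config.smooth_window
                    )
                    report.stats["expression_trend_first"] = float(smoothed[0])
                    report.stats["expression_trend_last"] = float(smoothed[-1])
            if part is not None and part.ensemble and part.solo:
                n = min(len(part.ensemble), len(part.solo))
                solo_sample = cooccupancy.sample_peaks(part.solo, n,
                                                      config.rng_seed)
                for kind, plist in (("ensemble", part.ensemble[:n]),
                                    ("solo", solo_sample)):
                    anchors = [(p.chrom, p.summit, ".") for p in plist]
                    pm = profiles.profile_matrix(
                        track, anchors, config.heatmap_halfwindow,
                        config.profile_bins, [p.name for p in plist],
                    )
                    avg = profiles.average_profile(pm)
                    report.stats[f"avg_profile_center_{kind}"] = float(
                        avg[pm.nbins // 2]
                    )
            _log_stage(report, stage)

        stage = "diffexpr"
        de_results = diffexpr.run_de(expr, config.de_alpha)
        path = os.path.join(outdir, "de_results.tsv")
        diffexpr.write_de_table(de_results, path)
        report.outputs["de_results"] = path
        decreased, increased = diffexpr.de_sets(
            de_results, config.de_alpha, config.de_use_adjusted
        )
        report.stats["n_decreased_after_kd"] = len(decreased)
        report.stats["n_increased_after_kd"] = len(increased)
        _log_stage(report, stage, decreased=len(decreased),
                   increased=len(increased))

        stage = "activity"
        distances = activity.nearest_peak_distance(genes, peaks_a_f)
        background = (expressed - decreased - increased) or None
        calls = activity.call_factor_direction(
            decreased, increased, distances, background, config.ks_alpha
        )
        report.stats["direction_labels"] = calls["labels"]
        for label, call in calls["calls"].items():
            report.stats[f"ks_d_plus_{label}"] = call.d_plus
            report.stats[f"ks_p_{label}"] = call.p
        path = os.path.join(outdir, "activity_calls.json")
        with open(path, "w") as fh:
            json.dump(
                {label: {"n_set": c.n_set, "n_background": c.n_background,
                         "d_plus": c.d_plus, "p": c.p,
                         "direction_claim": c.direction_claim}
                 for label, c in calls["calls"].items()},
                fh, indent=1, sort_keys=True,
            )
        report.outputs["activity_calls"] = path
        rp = activity.regulatory_potential_all(
            genes, peaks_a_f, config.rp_decay_distance, config.rp_horizon
        )
        active, repressive, shortfall = activity.select_top_regulated(
            de_results, rp, config.top_n
        )
        for name, lst in (("active", active), ("repressive", repressive)):
            path = os.path.join(outdir, f"top_{name}_genes.txt")
            with open(path, "w") as fh:
                fh.write("\n".join(lst) + ("\n" if lst else ""))
            report.outputs[f"top_{name}_genes"] = path
        report.stats["n_top_active"] = len(active)
        report.stats["n_top_repressive"] = len(repressive)
        if shortfall:
            report.stats["top_selection_shortfall"] = shortfall
        _log_stage(report, stage, labels=calls["labels"])

        stage = "motifs"
        if "genome" in inputs and part is not None and part.ensemble:
            genome = gio.read_fasta(inputs["genome"])
            chrom_lengths = {c: len(s) for c, s in genome.items()}
            pwm = motifs.load_builtin_pwm("rest_nrse")
            fg = motifs.summit_windows(part.ensemble, config.motif_window,
                                       chrom_lengths)
            bg = motifs.random_background_windows(
                chrom_lengths, config.motif_window, len(fg), config.rng_seed
            )
            enrich = motifs.motif_enrichment_test(fg, bg, genome, pwm)
            report.stats["motif_odds_ratio"] = enrich["odds_ratio"]
            report.stats["motif_p"] = enrich["p_value"]
            report.stats["motif_fg_hits"] = enrich["fg_hits"]
            report.stats["motif_bg_hits"] = enrich["bg_hits"]
            path = os.path.join(outdir, "motif_enrichment.json")
            with open(path, "w") as fh:
                json.dump(enrich, fh, indent=1, sort_keys=True)
            report.outputs["motif_enrichment"] = path
            _log_stage(report, stage, p=enrich["p_value"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    path = os.path.join(outdir, "run_report.json")
    report.to_json(path)
    report.outputs["run_report"] = path
    return report


def _log_stage(report: RunReport, stage: str, **counts: object) -> None:
    report.timestamps[stage] = time.time()
    log.info("stage %s done %s", stage,
             " ".join(f"{k}={v}" for k, v in counts.items()))
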