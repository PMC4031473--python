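"""Synthetic multi-factor ChIP-seq + knockdown-expression data with ground truth.

Emulates the statistical structure the pipeline consumes: a toy genome,
gene annotation with well-spaced TSSs, three factors' peak sets with a
controlled co-binding fraction and per-peak fold enrichment, coverage
tracks built from triangular kernels at the summits, a knockdown
expression matrix in which the designated factor's bound genes shift
after knockdown with an effect decaying in peak-to-TSS distance, and
motif instances planted under ensemble peaks.

Factor A is the knocked-down factor whose regulatory sign is planted;
factor B is the co-binding partner (solo/ensemble truth is defined
against B); factor C is an additional co-binding factor.  All randomness
derives from the single config seed, so a fixed seed gives byte-identical
output files.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .config import PipelineConfig
from .core import (
    ConfigurationError,
    CoverageTrack,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    Peak,
    ValidationError,
)
from . import io as gio

FACTOR_NAMES = ("TF_A", "TF_B", "TF_C")
PEAK_HALFWIDTH = 200     # bp each side of the summit
KERNEL_HALFWIDTH = 300   # bp, triangular coverage kernel
MIN_GENE_SPACING = 10_000  # bp between adjacent TSSs
# consensus planted for the motif-enrichment check (matches the shipped
# consensus-derived REST/NRSE matrix)
PLANTED_MOTIF = "TTCAGCACCACGGACAGCGCC"


@dataclass
class SyntheticConfig:
    """Generator conditions.

    Effect sizes are on the log2 expression scale: an activator-bound gene's
    knockdown mean drops by ``activator_effect * exp(-d / effect_decay_bp)``
    where d is the realized summit-to-TSS distance.
    """

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 500
    n_peaks: int = 300                 # per factor
    cobinding_fraction: float = 0.2    # of factor-A peaks co-bound by B (and C)
    promoter_binding_fraction: float = 0.6
    activator_effect: float = 2.0      # log2 units at d = 0
    repressor_effect: float = 2.0
    effect_decay_bp: float = 2000.0
    expression_noise_sd: float = 0.5
    motif_plant_rate_fg: float = 0.8   # ensemble-peak windows
    motif_plant_rate_bg: float = 0.1   # random background windows
    n_control: int = 4
    n_knockdown: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cobinding_fraction", "promoter_binding_fraction",
                     "motif_plant_rate_fg", "motif_plant_rate_bg"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.chrom_length <= 0 or self.n_genes <= 0 or self.n_peaks <= 0:
            raise ConfigurationError("sizes must be positive")
        if self.expression_noise_sd < 0:
            raise ConfigurationError("expression_noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring against pipeline output."""

    # gene_id -> factor -> realized min |summit - TSS| (inf if unbound)
    gene_distance: Dict[str, Dict[str, float]]
    # gene_id -> 'activated' | 'repressed' | None
    gene_role: Dict[str, Optional[str]]
    # gene_id -> planted knockdown shift (signed, log2 units)
    gene_effect: Dict[str, float]
    # factor -> peak name -> is_ensemble (vs TF_B; only for TF_A)
    ensemble_flag: Dict[str, bool]
    # peak name -> motif planted under the summit
    motif_flag: Dict[str, bool]
    bg_windows: List[Tuple[str, int, int]]
    bg_motif_flag: List[bool]
    tss_window: int

    def bound_genes(self, factor: str, window: float) -> Set[str]:
        return {g for g, d in self.gene_distance.items()
                if d.get(factor, math.inf) <= window}

    def to_json(self, path: str) -> None:
        payload = {
            "gene_distance": {
                g: {f: (None if math.isinf(d) else d) for f, d in m.items()}
                for g, m in self.gene_distance.items()
            },
            "gene_role": self.gene_role,
            "gene_effect": self.gene_effect,
            "ensemble_flag": self.ensemble_flag,
            "motif_flag": self.motif_flag,
            "bg_windows": self.bg_windows,
            "bg_motif_flag": self.bg_motif_flag,
            "tss_window": self.tss_window,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    chrom_lengths: Dict[str, int]
    genes: List[GeneModel]
    peaks: Dict[str, List[Peak]]
    truth: GroundTruth
    expression: ExpressionMatrix
    genome: Optional[Dict[str, str]] = None
    coverage: Dict[str, CoverageTrack] = field(default_factory=dict)

    def write(self, outdir: str) -> Dict[str, str]:
        """Emit all files the pipeline consumes; returns {kind: path}."""
        os.makedirs(outdir, exist_ok=True)
        paths: Dict[str, str] = {}
        if self.genome is not None:
            paths["genome"] = os.path.join(outdir, "genome.fa")
            gio.write_fasta(self.genome, paths["genome"])
        paths["genes"] = os.path.join(outdir, "genes.refflat")
        gio.write_gene_annotation(self.genes, paths["genes"])
        for factor, plist in self.peaks.items():
            key = f"peaks_{factor}"
            paths[key] = os.path.join(outdir, f"{factor}.narrowPeak")
            gio.write_peaks(plist, paths[key], format="narrowpeak")
        for factor, track in self.coverage.items():
            key = f"coverage_{factor}"
            paths[key] = os.path.join(outdir, f"{factor}.bedGraph")
            gio.write_coverage(track, paths[key])
        paths["expression"] = os.path.join(outdir, "expression.tsv")
        paths["conditions"] = os.path.join(outdir, "conditions.yaml")
        gio.write_expression(self.expression, paths["expression"],
                             paths["conditions"])
        paths["truth"] = os.path.join(outdir, "ground_truth.json")
        self.truth.to_json(paths["truth"])
        return paths


def _place_genes(cfg: SyntheticConfig, rng: np.random.Generator,
                 chroms: List[str]) -> List[GeneModel]:
    margin = 25_000
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    genes: List[GeneModel] = []
    gid = 0
    for chrom, n in zip(chroms, per_chrom):
        room = cfg.chrom_length - 2 * margin - (n - 1) * MIN_GENE_SPACING
        if room <= 0:
            raise ConfigurationError(
                f"{n} genes at {MIN_GENE_SPACING} bp spacing do not fit on a "
                f"{cfg.chrom_length} bp chromosome"
            )
        offsets = np.sort(rng.integers(0, room, size=n))
        tss_positions = margin + offsets + np.arange(n) * MIN_GENE_SPACING
        strands = rng.choice(["+", "-"], size=n)
        lengths = rng.integers(2_000, 8_000, size=n)
        for t, strand, length in zip(tss_positions, strands, lengths):
            t = int(t)
            length = int(length)
            if strand == "+":
                tx_start, tx_end = t, min(t + length, cfg.chrom_length)
            else:
                tx_start, tx_end = max(0, t + 1 - length), t + 1
            cds_start = tx_start + 200
            cds_end = tx_end - 200
            genes.append(GeneModel(
                f"G{gid:04d}", chrom, str(strand), tx_start, tx_end,
                cds_start, cds_end, (tx_start,), (tx_end,),
            ))
            gid += 1
    return genes


def _truncated_normal(rng: np.random.Generator, sd: float, bound: float,
                      size: int) -> np.ndarray:
    out = rng.normal(0.0, sd, size=size)
    bad = np.abs(out) > bound
    while bad.any():
        out[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(out) > bound
    return out


def _far_from(sorted_positions: np.ndarray, pos: int, min_dist: int) -> bool:
    if sorted_positions.size == 0:
        return True
    i = int(np.searchsorted(sorted_positions, pos))
    for j in (i - 1, i):
        if 0 <= j < sorted_positions.size and abs(int(sorted_positions[j]) - pos) < min_dist:
            return False
    return True


def _make_peak(factor: str, idx: int, chrom: str, summit: int,
               fold: float, chrom_length: int) -> Peak:
    start = max(0, summit - PEAK_HALFWIDTH)
    end = min(chrom_length, summit + PEAK_HALFWIDTH)
    return Peak(GenomicInterval(chrom, start, end, "."),
                f"{factor}_p{idx:04d}", summit, round(fold, 3), round(fold, 3))


def generate(config: SyntheticConfig,
             outdir: Optional[str] = None,
             include_genome: bool = True,
             include_coverage: bool = True) -> SyntheticDataset:
    """Generate a full synthetic dataset (optionally writing files).

    ``include_genome`` / ``include_coverage`` skip the sequence and
    coverage artifacts when a caller only needs peaks and expression;
    the random stream consumed for the remaining artifacts is unchanged,
    so shared components are identical either way.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_lengths = {c: cfg.chrom_length for c in chroms}

    genes = _place_genes(cfg, rng, chroms)
    tss_by_chrom: Dict[str, np.ndarray] = {
        c: np.sort(np.array([g.tss for g in genes if g.chrom == c]))
        for c in chroms
    }

    tss_window = 3000
    # --- factor A peaks -------------------------------------------------
    n_promoter = int(round(cfg.promoter_binding_fraction * cfg.n_peaks))
    if n_promoter > cfg.n_genes:
        raise ConfigurationError(
            "promoter peaks requested exceed the number of genes"
        )
    target_gene_idx = rng.choice(cfg.n_genes, size=n_promoter, replace=False)
    offsets = _truncated_normal(rng, 1000.0, tss_window, n_promoter)
    peaks_a: List[Peak] = []
    a_summits: Dict[str, List[int]] = {c: [] for c in chroms}
    folds = rng.uniform(2.0, 50.0, size=cfg.n_peaks)
    for k, (gi, off) in enumerate(zip(target_gene_idx, offsets)):
        gene = genes[int(gi)]
        summit = int(gene.tss + round(off))
        summit = min(max(summit, PEAK_HALFWIDTH),
                     cfg.chrom_length - PEAK_HALFWIDTH - 1)
        peaks_a.append(_make_peak("TF_A", k, gene.chrom, summit,
                                  folds[k], cfg.chrom_length))
        a_summits[gene.chrom].append(summit)
    # the rest: intergenic, > tss_window from every TSS, >= 1 kb apart
    k = n_promoter
    while k < cfg.n_peaks:
        chrom = chroms[int(rng.integers(cfg.n_chroms))]
        summit = int(rng.integers(PEAK_HALFWIDTH,
                                  cfg.chrom_length - PEAK_HALFWIDTH))
        if not _far_from(tss_by_chrom[chrom], summit, tss_window + 1):
            continue
        if not _far_from(np.sort(np.array(a_summits[chrom])), summit, 1000):
            continue
        peaks_a.append(_make_peak("TF_A", k, chrom, summit,
                                  folds[k], cfg.chrom_length))
        a_summits[chrom].append(summit)
        k += 1
    a_summit_sorted = {c: np.sort(np.array(v)) for c, v in a_summits.items()}

    # --- partner factors B and C ---------------------------------------
    peaks_other: Dict[str, List[Peak]] = {}
    ensemble_flag: Dict[str, bool] = {p.name: False for p in peaks_a}
    for factor in ("TF_B", "TF_C"):
        n_co = int(round(cfg.cobinding_fraction * cfg.n_peaks))
        co_idx = rng.choice(cfg.n_peaks, size=n_co, replace=False)
        plist: List[Peak] = []
        folds_f = rng.uniform(2.0, 50.0, size=cfg.n_peaks)
        for j, ai in enumerate(co_idx):
            a_peak = peaks_a[int(ai)]
            jitter = int(rng.integers(-100, 101))
            summit = min(max(a_peak.summit + jitter, PEAK_HALFWIDTH),
                         cfg.chrom_length - PEAK_HALFWIDTH - 1)
            plist.append(_make_peak(factor, j, a_peak.chrom, summit,
                                    folds_f[j], cfg.chrom_length))
            if factor == "TF_B":
                ensemble_flag[a_peak.name] = True
        j = n_co
        while j < cfg.n_peaks:
            chrom = chroms[int(rng.integers(cfg.n_chroms))]
            summit = int(rng.integers(PEAK_HALFWIDTH,
                                      cfg.chrom_length - PEAK_HALFWIDTH))
            # keep planted-solo A peaks truly solo
            if not _far_from(a_summit_sorted[chrom], summit, 1000):
                continue
            plist.append(_make_peak(factor, j, chrom, summit,
                                    folds_f[j], cfg.chrom_length))
            j += 1
        peaks_other[factor] = plist
    peaks = {"TF_A": peaks_a, **peaks_other}

    # --- realized gene-factor distances --------------------------------
    from .activity import nearest_peak_distance

    gene_distance: Dict[str, Dict[str, float]] = {g.gene_id: {} for g in genes}
    for factor, plist in peaks.items():
        dist = nearest_peak_distance(genes, plist)
        for gid, d in dist.items():
            gene_distance[gid][factor] = d

    # --- expression with planted knockdown effects ---------------------
    gene_role: Dict[str, Optional[str]] = {}
    gene_effect: Dict[str, float] = {}
    control_mean = rng.normal(8.0, 1.0, size=cfg.n_genes)
    kd_mean = control_mean.copy()
    for i, gene in enumerate(genes):
        d = gene_distance[gene.gene_id]["TF_A"]
        role: Optional[str] = None
        effect = 0.0
        if d <= tss_window:
            has_act = cfg.activator_effect > 0
            has_rep = cfg.repressor_effect > 0
            if has_act and has_rep:
                role = "activated" if rng.random() < 0.5 else "repressed"
            elif has_act:
                role = "activated"
            elif has_rep:
                role = "repressed"
            if role == "activated":
                effect = -cfg.activator_effect * math.exp(-d / cfg.effect_decay_bp)
            elif role == "repressed":
                effect = cfg.repressor_effect * math.exp(-d / cfg.effect_decay_bp)
        gene_role[gene.gene_id] = role
        gene_effect[gene.gene_id] = effect
        kd_mean[i] += effect
    n_s = cfg.n_control + cfg.n_knockdown
    noise = rng.normal(0.0, cfg.expression_noise_sd, size=(cfg.n_genes, n_s))
    values = np.concatenate([
        control_mean[:, None] + noise[:, :cfg.n_control],
        kd_mean[:, None] + noise[:, cfg.n_control:],
    ], axis=1)
    sample_ids = ([f"ctrl_{i + 1}" for i in range(cfg.n_control)]
                  + [f"kd_{i + 1}" for i in range(cfg.n_knockdown)])
    condition_map = {s: ("control" if s.startswith("ctrl") else "knockdown")
                     for s in sample_ids}
    expression = ExpressionMatrix([g.gene_id for g in genes], sample_ids,
                                  values, condition_map)

    # --- genome and planted motifs -------------------------------------
    genome: Optional[Dict[str, str]] = None
    motif_flag: Dict[str, bool] = {p.name: False for p in peaks_a}
    bg_windows: List[Tuple[str, int, int]] = []
    bg_motif_flag: List[bool] = []
    if include_genome:
        arrays = {
            c: rng.integers(0, 4, size=cfg.chrom_length).astype(np.uint8)
            for c in chroms
        }
        motif_codes = np.array(
            ["ACGT".index(b) for b in PLANTED_MOTIF], dtype=np.uint8
        )
        L = len(PLANTED_MOTIF)
        for p in peaks_a:
            if not ensemble_flag[p.name]:
                continue
            if rng.random() < cfg.motif_plant_rate_fg:
                start = p.summit - L // 2
                arrays[p.chrom][start:start + L] = motif_codes
                motif_flag[p.name] = True
        n_bg = sum(ensemble_flag.values())
        width = 600
        while len(bg_windows) < n_bg:
            chrom = chroms[int(rng.integers(cfg.n_chroms))]
            start = int(rng.integers(0, cfg.chrom_length - width))
            # background windows stay clear of real peaks
            if not _far_from(a_summit_sorted[chrom], start + width // 2, 1500):
                continue
            planted = bool(rng.random() < cfg.motif_plant_rate_bg)
            if planted:
                mid = start + width // 2 - L // 2
                arrays[chrom][mid:mid + L] = motif_codes
            bg_windows.append((chrom, start, start + width))
            bg_motif_flag.append(planted)
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        genome = {c: lut[a].tobytes().decode() for c, a in arrays.items()}

    # --- coverage tracks ------------------------------------------------
    coverage: Dict[str, CoverageTrack] = {}
    if include_coverage:
        for factor, plist in peaks.items():
            coverage[factor] = coverage_from_peaks(plist, chrom_lengths)

    truth = GroundTruth(gene_distance, gene_role, gene_effect,
                        ensemble_flag, motif_flag, bg_windows,
                        bg_motif_flag, tss_window)
    ds = SyntheticDataset(cfg, chrom_lengths, genes, peaks, truth,
                          expression, genome, coverage)
    if outdir is not None:
        ds.write(outdir)
    return ds


def coverage_from_peaks(peaks: Sequence[Peak],
                        chrom_lengths: Dict[str, int]) -> CoverageTrack:
    """Sum of triangular kernels (half-width 300 bp) scaled by fold enrichment.

    The discrete kernel at summit s has value fold * (1 - |x - s|/300) at
    base x, so its total mass is exactly 300 * fold.
    """
    h = KERNEL_HALFWIDTH
    by_chrom: Dict[str, List[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, plist in by_chrom.items():
        L = chrom_lengths[chrom]
        spans = sorted(
            ((max(0, p.summit - h + 1), min(L, p.summit + h), p) for p in plist),
            key=lambda t: (t[0], t[1]),
        )
        # merge overlapping spans into groups
        groups: List[List[Tuple[int, int, Peak]]] = []
        for span in spans:
            if groups and span[0] < groups[-1][-1][1]:
                groups[-1].append(span)
            else:
                groups.append([span])
        starts_all, values_all = [], []
        for group in groups:
            lo = min(s for s, _, _ in group)
            hi = max(e for _, e, _ in group)
            arr = np.zeros(hi - lo)
            for s, e, p in group:
                x = np.arange(s, e)
                arr[s - lo:e - lo] += p.fold_enrichment * (
                    1.0 - np.abs(x - p.summit) / h
                )
            nz = arr > 0
            pos = np.arange(lo, hi)[nz]
            starts_all.append(pos)
            values_all.append(arr[nz])
        if starts_all:
            starts = np.concatenate(starts_all)
            order = np.argsort(starts, kind="stable")
            starts = starts[order].astype(np.int64)
            values = np.concatenate(values_all)[order]
            runs[chrom] = (starts, starts + 1, values)
    return CoverageTrack(runs)


def truth_report(
    dataset: SyntheticDataset,
    target_genes: Set[str],
    used_peak_names: Optional[Set[str]] = None,
    ensemble_names: Optional[Set[str]] = None,
    solo_names: Optional[Set[str]] = None,
    direction_labels: Optional[Sequence[str]] = None,
    window: Optional[int] = None,
) -> Dict[str, float]:
    """Recovery metrics of pipeline outputs against the planted truth.

    Target sensitivity/specificity are computed against the genes that
    truly have a used factor-A peak summit within ``window`` of a TSS
    (recomputed from realized coordinates so peak filtering upstream is
    respected).  Ensemble accuracy compares the solo/ensemble partition
    with the planted co-binding flags; direction correctness checks the
    activator/repressor labels against the planted effects.
    """
    from .activity import nearest_peak_distance

    truth = dataset.truth
    window = window if window is not None else truth.tss_window
    peaks_a = dataset.peaks["TF_A"]
    if used_peak_names is not None:
        peaks_a = [p for p in peaks_a if p.name in used_peak_names]
    dist = nearest_peak_distance(dataset.genes, peaks_a)
    qualifying = {g for g, d in dist.items() if d <= window}
    all_genes = set(dist)
    out: Dict[str, float] = {}
    if qualifying:
        out["target_sensitivity"] = len(target_genes & qualifying) / len(qualifying)
    negatives = all_genes - qualifying
    if negatives:
        out["target_specificity"] = (
            len(negatives - target_genes) / len(negatives)
        )
    if ensemble_names is not None and solo_names is not None:
        names = ensemble_names | solo_names
        correct = sum(
            1 for n in names
            if (n in ensemble_names) == truth.ensemble_flag.get(n, False)
        )
        if names:
            out["ensemble_accuracy"] = correct / len(names)
    if direction_labels is not None:
        expected = set()
        if dataset.config.activator_effect > 0:
            expected.add("activator evidence")
        if dataset.config.repressor_effect > 0:
            expected.add("repressor evidence")
        out["direction_correct"] = float(set(direction_labels) == expected)
    return out
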