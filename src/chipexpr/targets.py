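"""Peak-to-gene target assignment by a strand-aware TSS window.

A gene is a target of a factor when some peak summit lies within
``window`` bp of the gene's TSS (inclusive boundary).  Distances are
signed: positive = downstream of the TSS in gene orientation.
With multiple transcripts per gene id, a gene is a target if ANY
transcript's TSS qualifies, and its distance is the minimal |distance|
over transcripts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np

from .core import ConfigurationError, ExpressionMatrix, GeneModel, Peak

FEATURE_CATEGORIES = (
    "promoter", "5'UTR", "3'UTR", "coding exon", "intron", "intergenic",
)


@dataclass
class TargetMap:
    """Per-gene list of (peak index, signed summit-to-TSS distance in bp)."""

    assignments: Dict[str, List[Tuple[int, int]]]
    window: int

    @property
    def target_genes(self) -> Set[str]:
        return set(self.assignments)

    def distance(self, gene_id: str) -> int:
        """Signed distance of the closest qualifying peak (min |d|)."""
        return min(self.assignments[gene_id], key=lambda t: (abs(t[1]), t[1]))[1]

    def to_records(self, peaks: Sequence[Peak]) -> List[Tuple[str, str, int]]:
        out = []
        for gene_id in sorted(self.assignments):
            for idx, dist in self.assignments[gene_id]:
                out.append((gene_id, peaks[idx].name, dist))
        return out


def tss(gene: GeneModel) -> int:
    """0-based coordinate of the first transcribed base."""
    return gene.tss


def signed_distance(summit: int, gene: GeneModel) -> int:
    """summit - TSS, sign flipped for minus-strand genes (positive = downstream)."""
    d = summit - gene.tss
    return d if gene.strand == "+" else -d


def assign_targets(
    peaks: Sequence[Peak], genes: Sequence[GeneModel], window: int
) -> TargetMap:
    """Map peaks to target genes: |summit - TSS| <= window, per transcript.

    Returns a :class:`TargetMap` keyed by gene id, listing every qualifying
    peak with its signed distance.  For multi-transcript genes each peak is
    listed once with its minimal-|d| distance over that gene's transcripts.
    """
    if window <= 0:
        raise ConfigurationError("window must be positive")
    if not genes:
        raise ConfigurationError("empty gene list")
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for i, p in enumerate(peaks):
        by_chrom.setdefault(p.chrom, []).append((p.summit, i))
    for lst in by_chrom.values():
        lst.sort()

    # gene_id -> peak index -> best signed distance over transcripts
    best: Dict[str, Dict[int, int]] = {}
    for gene in genes:
        if gene.chrom not in by_chrom:
            continue
        summits = by_chrom[gene.chrom]
        positions = [s for s, _ in summits]
        t = gene.tss
        lo = np.searchsorted(positions, t - window, side="left")
        hi = np.searchsorted(positions, t + window, side="right")
        for summit, idx in summits[lo:hi]:
            d = signed_distance(summit, gene)
            slot = best.setdefault(gene.gene_id, {})
            if idx not in slot or (abs(d), d) < (abs(slot[idx]), slot[idx]):
                slot[idx] = d
    assignments = {
        g: sorted(((i, d) for i, d in slots.items()))
        for g, slots in best.items()
    }
    return TargetMap(assignments, window)


def _summit_in_exon(summit: int, gene: GeneModel) -> bool:
    for s, e in zip(gene.exon_starts, gene.exon_ends):
        if s <= summit < e:
            return True
    return False


def _classify_against_gene(summit: int, gene: GeneModel, promoter_window: int) -> str:
    """Category of a summit relative to one gene (or 'intergenic')."""
    if abs(summit - gene.tss) <= promoter_window:
        return "promoter"
    if not (gene.tx_start <= summit < gene.tx_end):
        return "intergenic"
    if gene.cds_start is not None and gene.cds_end is not None:
        before_cds = summit < gene.cds_start
        after_cds = summit >= gene.cds_end
        if (before_cds and gene.strand == "+") or (after_cds and gene.strand == "-"):
            utr = "5'UTR"
        elif before_cds or after_cds:
            utr = "3'UTR"
        else:
            utr = None
        if utr is not None:
            return utr if _summit_in_exon(summit, gene) or not gene.exon_starts else "intron"
        if _summit_in_exon(summit, gene) or not gene.exon_starts:
            return "coding exon"
        return "intron"
    # no CDS annotation: transcribed region counts as exon/intron only
    if _summit_in_exon(summit, gene) or not gene.exon_starts:
        return "coding exon"
    return "intron"


def classify_peak_locations(
    peaks: Sequence[Peak], genes: Sequence[GeneModel], promoter_window: int = 3000
) -> Dict[str, Tuple[int, float]]:
    """Genome-feature distribution of peak summits.

    Each peak gets exactly one category by summit position with precedence
    promoter > 5'UTR > 3'UTR > coding exon > intron > intergenic (evaluated
    over all genes on the summit's chromosome).  Returns
    category -> (count, fraction).
    """
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    precedence = {cat: i for i, cat in enumerate(FEATURE_CATEGORIES)}
    counts = {cat: 0 for cat in FEATURE_CATEGORIES}
    for p in peaks:
        cat = "intergenic"
        for gene in by_chrom.get(p.chrom, ()):
            c = _classify_against_gene(p.summit, gene, promoter_window)
            if precedence[c] < precedence[cat]:
                cat = c
            if cat == "promoter":
                break
        counts[cat] += 1
    total = max(1, len(peaks))
    return {cat: (n, n / total) for cat, n in counts.items()}


def expressed_genes(expr: ExpressionMatrix, threshold: float,
                    annotated_ids: Iterable[str] | None = None) -> Set[str]:
    """Genes whose mean control-condition value >= threshold.

    Ids absent from ``annotated_ids`` (when given) are retained with a
    warning, so expression-only genes stay visible downstream.
    """
    control = expr.columns_for("control")
    means = control.mean(axis=1)
    selected = {rid for rid, m in zip(expr.row_ids, means) if m >= threshold}
    if annotated_ids is not None:
        unknown = selected - set(annotated_ids)
        if unknown:
            warnings.warn(
                f"{len(unknown)} expressed gene ids missing from annotation "
                f"(e.g. {sorted(unknown)[:3]}); retained",
                stacklevel=2,
            )
    return selected


def write_target_map(tmap: TargetMap, peaks: Sequence[Peak], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tpeak_name\tdistance\n")
        for gene_id, peak_name, dist in tmap.to_records(peaks):
            fh.write(f"{gene_id}\t{peak_name}\t{dist}\n")


def write_feature_distribution(dist: Dict[str, Tuple[int, float]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("category\tcount\tfraction\n")
        for cat in FEATURE_CATEGORIES:
            n, frac = dist[cat]
            fh.write(f"{cat}\t{n}\t{frac:.6g}\n")
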