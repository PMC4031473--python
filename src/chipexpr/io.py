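"""Readers and writers for the pipeline's external formats.

Supported inputs: BED6 and ENCODE narrowPeak peak files, refFlat and BED12
gene annotation, bedGraph and fixedStep WIG coverage, FASTA genomes, TSV
expression matrices with a YAML sample-condition map.

Coordinates are converted to 0-based half-open on read (refFlat and BED are
already half-open; WIG ``start`` is 1-based and converted).
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .core import (
    ConfigurationError,
    CoverageTrack,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    ParseError,
    Peak,
    ValidationError,
)


def _lines(path: str) -> Iterable[Tuple[int, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_peaks(path: str, format: str = "narrowpeak") -> List[Peak]:
    """Read a peak file into a list of :class:`Peak`.

    narrowPeak summits come from column 10 (offset from start; ``-1`` means
    unknown and falls back to the interval midpoint).  BED6 has no summit
    column, so the midpoint is used, rounding down.  Fold enrichment is
    narrowPeak column 7, else 0.
    """
    fmt = format.lower()
    if fmt not in ("bed6", "narrowpeak"):
        raise ConfigurationError(f"unknown peak format {format!r}")
    need = 6 if fmt == "bed6" else 10
    peaks: List[Peak] = []
    for lineno, line in _lines(path):
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) < need:
            raise ParseError(
                f"{path}:{lineno}: expected >= {need} columns, got {len(cols)}"
            )
        try:
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3]
            score = float(cols[4]) if cols[4] != "." else 0.0
            strand = cols[5]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if start >= end:
            raise ValidationError(f"{path}:{lineno}: start >= end")
        interval = GenomicInterval(chrom, start, end, strand)
        if fmt == "narrowpeak":
            try:
                fold = float(cols[6])
                score = float(cols[8])  # -log10(qValue)
                offset = int(cols[9])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            summit = start + offset if offset >= 0 else (start + end) // 2
            peaks.append(Peak(interval, name, summit, fold, score))
        else:
            peaks.append(Peak(interval, name, (start + end) // 2, 0.0, score))
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str, format: str = "narrowpeak") -> None:
    """Write peaks; round-trips all semantic fields of :func:`read_peaks`."""
    fmt = format.lower()
    with open(path, "w") as fh:
        for p in peaks:
            base = [p.chrom, str(p.start), str(p.end), p.name, "0",
                    p.interval.strand]
            if fmt == "narrowpeak":
                base[4] = "0"
                base += [f"{p.fold_enrichment:g}", "-1", f"{p.score:g}",
                         str(p.summit - p.start)]
            else:
                base[4] = f"{p.score:g}"
            fh.write("\t".join(base) + "\n")


def read_gene_annotation(path: str, format: str = "refflat") -> List[GeneModel]:
    """Read gene models from refFlat or BED12.

    One :class:`GeneModel` per transcript row; duplicate gene ids are
    retained (de-duplication is caller policy).  refFlat columns:
    geneName, name, chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    exonCount, exonStarts, exonEnds.
    """
    fmt = format.lower()
    if fmt not in ("refflat", "bed12"):
        raise ConfigurationError(f"unknown annotation format {format!r}")
    genes: List[GeneModel] = []
    for lineno, line in _lines(path):
        cols = line.split("\t") if "\t" in line else line.split()
        try:
            if fmt == "refflat":
                if len(cols) < 11:
                    raise ParseError(
                        f"{path}:{lineno}: refFlat needs 11 columns"
                    )
                gene_id, _name, chrom, strand = cols[0], cols[1], cols[2], cols[3]
                tx_start, tx_end = int(cols[4]), int(cols[5])
                cds_start, cds_end = int(cols[6]), int(cols[7])
                exon_starts = tuple(int(x) for x in cols[9].rstrip(",").split(",") if x)
                exon_ends = tuple(int(x) for x in cols[10].rstrip(",").split(",") if x)
            else:
                if len(cols) < 12:
                    raise ParseError(f"{path}:{lineno}: BED12 needs 12 columns")
                chrom, tx_start, tx_end = cols[0], int(cols[1]), int(cols[2])
                gene_id, strand = cols[3], cols[5]
                cds_start, cds_end = int(cols[6]), int(cols[7])
                sizes = [int(x) for x in cols[10].rstrip(",").split(",") if x]
                offsets = [int(x) for x in cols[11].rstrip(",").split(",") if x]
                exon_starts = tuple(tx_start + o for o in offsets)
                exon_ends = tuple(s + z for s, z in zip(exon_starts, sizes))
        except ParseError:
            raise
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if strand not in ("+", "-"):
            raise ValidationError(
                f"{path}:{lineno}: unknown strand symbol {strand!r}"
            )
        if cds_start >= cds_end:  # BED convention for non-coding: thickStart==thickEnd
            cds_start = cds_end = None  # type: ignore[assignment]
        genes.append(
            GeneModel(gene_id, chrom, strand, tx_start, tx_end,
                      cds_start, cds_end, exon_starts, exon_ends)
        )
    return genes


def write_gene_annotation(genes: Iterable[GeneModel], path: str) -> None:
    """Write gene models as refFlat (transcript name = gene id)."""
    with open(path, "w") as fh:
        for g in genes:
            cds_start = g.cds_start if g.cds_start is not None else g.tx_start
            cds_end = g.cds_end if g.cds_end is not None else g.tx_start
            ex_s = g.exon_starts or (g.tx_start,)
            ex_e = g.exon_ends or (g.tx_end,)
            fh.write("\t".join([
                g.gene_id, g.gene_id, g.chrom, g.strand,
                str(g.tx_start), str(g.tx_end), str(cds_start), str(cds_end),
                str(len(ex_s)),
                ",".join(map(str, ex_s)) + ",",
                ",".join(map(str, ex_e)) + ",",
            ]) + "\n")


def read_coverage(path: str, format: str = "bedgraph") -> CoverageTrack:
    """Read per-base coverage from bedGraph or fixedStep WIG.

    Positions not covered by any record are 0.  Overlapping bedGraph
    records raise :class:`ValidationError`.
    """
    fmt = format.lower()
    if fmt not in ("bedgraph", "fixedstep_wig"):
        raise ConfigurationError(f"unknown coverage format {format!r}")
    records: List[Tuple[str, int, int, float]] = []
    if fmt == "bedgraph":
        for lineno, line in _lines(path):
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 4:
                raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
            try:
                records.append((cols[0], int(cols[1]), int(cols[2]), float(cols[3])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    else:
        chrom, pos, step, span = None, 0, 1, 1
        for lineno, line in _lines(path):
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=", 1) for tok in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1  # WIG is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                continue
            if chrom is None:
                raise ParseError(f"{path}:{lineno}: value before fixedStep header")
            try:
                value = float(line.split()[0])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append((chrom, pos, pos + span, value))
            pos += step
    return CoverageTrack.from_runs(records)


def write_coverage(track: CoverageTrack, path: str) -> None:
    """Write a track as bedGraph, merging adjacent equal-valued runs."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.runs(chrom)
            i = 0
            n = len(starts)
            while i < n:
                j = i
                while (j + 1 < n and starts[j + 1] == ends[j]
                       and values[j + 1] == values[i]):
                    j += 1
                if values[i] != 0:
                    fh.write(f"{chrom}\t{starts[i]}\t{ends[j]}\t{values[i]:g}\n")
                i = j + 1


def read_expression(path: str, condition_map_path: str) -> ExpressionMatrix:
    """Read a TSV expression matrix (rows = genes/probes) plus YAML condition map.

    The condition map must cover every sample with a condition in
    {control, knockdown}; rows with non-numeric cells are rejected with
    the offending row ids listed.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    with open(condition_map_path) as fh:
        cond_map = yaml.safe_load(fh)
    if not isinstance(cond_map, dict):
        raise ConfigurationError("condition map must be a mapping sample -> condition")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(values).all(axis=1)
    if bad.any():
        raise ValidationError(
            f"non-numeric expression values in rows {list(df.index[bad][:5])}"
        )
    return ExpressionMatrix(
        row_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        values=values,
        condition_map={str(k): v for k, v in cond_map.items()},
    )


def write_expression(expr: ExpressionMatrix, path: str,
                     condition_map_path: Optional[str] = None) -> None:
    df = pd.DataFrame(expr.values, index=expr.row_ids, columns=expr.sample_ids)
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")
    if condition_map_path:
        with open(condition_map_path, "w") as fh:
            yaml.safe_dump(dict(expr.condition_map), fh, sort_keys=True)


def read_fasta(path: str) -> Dict[str, str]:
    """Read a FASTA into {name: uppercase sequence}.

    Record name is the first whitespace-delimited token.  Duplicate names
    and empty sequences raise :class:`ValidationError`.
    """
    genome: Dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        name = rec.id
        if name in genome:
            raise ValidationError(f"duplicate FASTA record {name!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValidationError(f"empty sequence for record {name!r}")
        genome[name] = seq
    return genome


def write_fasta(genome: Dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
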