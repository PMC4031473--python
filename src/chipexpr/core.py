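"""Core genomic and expression data model.

All coordinates are BED-convention 0-based half-open intervals.  Strand is
``'+'``, ``'-'`` or ``'.'`` (unstranded).  Chromosome names are matched by
exact string equality; no ``chr``-prefix aliasing is performed unless a
reader is explicitly asked to normalise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np


class ValidationError(ValueError):
    """Input violates a structural invariant (coordinates, strand, values)."""


class ConfigurationError(ValueError):
    """Inconsistent or incomplete run configuration."""


class ParseError(ValueError):
    """A record in an input file could not be parsed."""


VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Overlap length in bp; 0 for different chromosomes or disjoint."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """A called binding site with its summit and enrichment statistics.

    ``summit`` is an absolute 0-based coordinate inside the interval.
    ``fold_enrichment`` is the ChIP-over-background ratio at the summit
    (narrowPeak column 7); ``score`` carries the caller's score column.
    """

    interval: GenomicInterval
    name: str = "."
    summit: int = -1
    fold_enrichment: float = 0.0
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.summit < 0:
            object.__setattr__(
                self, "summit", (self.interval.start + self.interval.end) // 2
            )
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.fold_enrichment < 0:
            raise ValidationError("fold_enrichment must be non-negative")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class GeneModel:
    """A transcript with a strand-aware TSS.

    ``cds_start``/``cds_end`` (half-open) are optional and only needed for
    UTR/exon classification of peak locations.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    exon_starts: Tuple[int, ...] = ()
    exon_ends: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene strand must be + or -, got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValidationError("tx_start must be < tx_end")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValidationError("exon_starts / exon_ends length mismatch")

    @property
    def tss(self) -> int:
        """0-based position of the first transcribed base."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


class CoverageTrack:
    """Run-length encoded non-negative per-base signal.

    Positions not covered by any run have value 0.  Runs within a chromosome
    are sorted and non-overlapping.  A prefix-integral per chromosome makes
    interval means O(log n).
    """

    def __init__(self, runs: Mapping[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # runs: chrom -> (starts, ends, values), assumed validated by from_runs
        self._runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = dict(runs)
        self._prefix: Dict[str, np.ndarray] = {}
        for chrom, (starts, ends, values) in self._runs.items():
            mass = (ends - starts) * values
            self._prefix[chrom] = np.concatenate([[0.0], np.cumsum(mass)])

    @classmethod
    def from_runs(
        cls, records: Iterable[Tuple[str, int, int, float]]
    ) -> "CoverageTrack":
        """Build from (chrom, start, end, value) records, sorting per chromosome.

        Raises :class:`ValidationError` on negative values or overlapping runs.
        """
        per_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if value < 0:
                raise ValidationError(
                    f"negative coverage value {value} at {chrom}:{start}-{end}"
                )
            if not (0 <= start < end):
                raise ValidationError(f"bad run [{start}, {end}) on {chrom}")
            per_chrom.setdefault(chrom, []).append((start, end, value))
        runs = {}
        for chrom, recs in per_chrom.items():
            recs.sort()
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            values = np.array([r[2] for r in recs], dtype=np.float64)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.nonzero(starts[1:] < ends[:-1])[0][0])
                raise ValidationError(
                    f"overlapping coverage runs on {chrom} near position {starts[i + 1]}"
                )
            runs[chrom] = (starts, ends, values)
        return cls(runs)

    @property
    def chroms(self) -> List[str]:
        return sorted(self._runs)

    def value_at(self, chrom: str, pos: int) -> float:
        """Signal value at a single position (0 where uncovered)."""
        if chrom not in self._runs:
            return 0.0
        starts, ends, values = self._runs[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Total signal mass (value x bp) over [start, end)."""
        if chrom not in self._runs or end <= start:
            return 0.0
        starts, ends, values = self._runs[chrom]
        prefix = self._prefix[chrom]

        def cum(pos: int) -> float:
            i = int(np.searchsorted(starts, pos, side="right")) - 1
            if i < 0:
                return 0.0
            total = prefix[i]
            covered = min(pos, int(ends[i])) - int(starts[i])
            if covered > 0:
                total += covered * values[i]
            return float(total)

        return cum(end) - cum(start)

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base signal over [start, end) (uncovered bases count as 0)."""
        if end <= start:
            return 0.0
        return self.integral(chrom, start, end) / (end - start)

    def total_mass(self) -> float:
        return float(sum(p[-1] for p in self._prefix.values()))

    def runs(self, chrom: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._runs.get(
            chrom,
            (
                np.empty(0, dtype=np.int64),
                np.empty(0, dtype=np.int64),
                np.empty(0, dtype=np.float64),
            ),
        )


@dataclass
class ExpressionMatrix:
    """Genes/probes x samples expression values with a condition map.

    ``condition_map`` assigns every sample to ``'control'`` or ``'knockdown'``.
    """

    row_ids: List[str]
    sample_ids: List[str]
    values: np.ndarray
    condition_map: Dict[str, str]

    VALID_CONDITIONS = ("control", "knockdown")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = [self.row_ids[i] for i in np.nonzero(
                ~np.isfinite(self.values).all(axis=1))[0][:5]]
            raise ValidationError(f"non-finite expression values in rows {bad}")
        for s in self.sample_ids:
            if s not in self.condition_map:
                raise ConfigurationError(f"sample {s!r} missing from condition map")
            if self.condition_map[s] not in self.VALID_CONDITIONS:
                raise ConfigurationError(
                    f"unknown condition {self.condition_map[s]!r} for sample {s!r}"
                )

    def samples_for(self, condition: str) -> List[str]:
        return [s for s in self.sample_ids if self.condition_map[s] == condition]

    def columns_for(self, condition: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.sample_ids)
               if self.condition_map[s] == condition]
        return self.values[:, idx]

    def row(self, row_id: str) -> np.ndarray:
        return self.values[self.row_ids.index(row_id)]
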