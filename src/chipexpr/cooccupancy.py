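"""Co-binding quantification.

Fold-enrichment filtering, peak interval overlap, the solo/ensemble
partition of one factor's peaks by a partner factor's co-occupancy, and
target-gene set overlap significance under the hypergeometric model.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .core import Peak, ValidationError


@dataclass
class PeakPartition:
    """A factor's peaks split by partner co-occupancy (>= min_bp overlap)."""

    ensemble: List[Peak]
    solo: List[Peak]
    partner_factor: str = ""

    def __post_init__(self) -> None:
        # structural invariant: disjoint and exhaustive by construction
        assert not (set(id(p) for p in self.ensemble)
                    & set(id(p) for p in self.solo))

    @property
    def n_total(self) -> int:
        return len(self.ensemble) + len(self.solo)


@dataclass
class OverlapResult:
    """Gene-set overlap with its hypergeometric upper-tail p-value."""

    n_a: int
    n_b: int
    n_universe: int
    overlap: int
    p_value: float

    def __post_init__(self) -> None:
        assert self.overlap <= min(self.n_a, self.n_b)
        assert max(self.n_a, self.n_b) <= self.n_universe
        assert 0.0 <= self.p_value <= 1.0


def filter_by_fold(peaks: Sequence[Peak], min_fold: float) -> List[Peak]:
    """Peaks with fold_enrichment strictly greater than ``min_fold``."""
    return [p for p in peaks if p.fold_enrichment > min_fold]


def _trees(peaks: Sequence[Peak]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for i, p in enumerate(peaks):
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, i)
    return trees


def interval_overlaps(
    peaks_a: Sequence[Peak], peaks_b: Sequence[Peak], min_bp: int = 1
) -> List[Tuple[int, int]]:
    """Index pairs (i, j) whose intervals share >= min_bp on the same chromosome."""
    if min_bp < 1:
        raise ValidationError("min_bp must be >= 1")
    trees_b = _trees(peaks_b)
    pairs: List[Tuple[int, int]] = []
    for i, p in enumerate(peaks_a):
        tree = trees_b.get(p.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(p.start, p.end):
            if min(p.end, hit.end) - max(p.start, hit.begin) >= min_bp:
                pairs.append((i, hit.data))
    pairs.sort()
    return pairs


def partition_solo_ensemble(
    peaks_a: Sequence[Peak], peaks_b: Sequence[Peak],
    min_bp: int = 1, partner_factor: str = "",
) -> PeakPartition:
    """Split A's peaks into ensemble (overlap >= min_bp with some B peak) and solo."""
    hit_a = {i for i, _ in interval_overlaps(peaks_a, peaks_b, min_bp)}
    ensemble = [p for i, p in enumerate(peaks_a) if i in hit_a]
    solo = [p for i, p in enumerate(peaks_a) if i not in hit_a]
    return PeakPartition(ensemble, solo, partner_factor)


def sample_peaks(peaks: Sequence[Peak], n: int, seed: int) -> List[Peak]:
    """Uniform sample of n peaks without replacement, reproducible by seed."""
    if n > len(peaks):
        raise ValidationError(f"cannot sample {n} from {len(peaks)} peaks")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(peaks), size=n, replace=False)
    return [peaks[i] for i in idx]


def hypergeom_tail(k: int, n_universe: int, n_a: int, n_b: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, |A|, |B|): upper tail, observed included."""
    p = float(hypergeom.sf(k - 1, n_universe, n_a, n_b))
    return min(1.0, max(0.0, p))


def target_overlap_significance(
    set_a: Set[str], set_b: Set[str], universe: Set[str]
) -> OverlapResult:
    """Upper-tail hypergeometric p for the overlap of two gene sets.

    p = P(X >= k) with X ~ Hypergeom(N, |A|, |B|), k = |A ∩ B|; the
    observed overlap is included in the tail.
    """
    if not set_a <= universe or not set_b <= universe:
        raise ValidationError("gene sets must be subsets of the universe")
    n = len(universe)
    k = len(set_a & set_b)
    return OverlapResult(len(set_a), len(set_b), n, k,
                         hypergeom_tail(k, n, len(set_a), len(set_b)))


def venn_counts(sets: Dict[str, Set[str]]) -> Dict[Tuple[str, ...], int]:
    """Disjoint region counts for 2 or 3 named sets.

    Keys are sorted tuples of the set names whose exclusive intersection the
    region is; counts sum to the size of the union.
    """
    names = sorted(sets)
    if len(names) not in (2, 3):
        raise ValidationError("venn_counts requires 2 or 3 sets")
    out: Dict[Tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for members in combinations(names, r):
            inside = set.intersection(*(sets[m] for m in members))
            outside = set.union(
                set(), *(sets[m] for m in names if m not in members)
            )
            out[members] = len(inside - outside)
    return out
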