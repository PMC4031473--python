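"""Known-motif (PWM) scanning and enrichment in summit-centred windows.

Peaks are trimmed/extended to fixed-width windows centred on their
summits; a position weight matrix is scanned over both strands at every
offset, and a window "has a hit" when any log-odds score reaches the
threshold.  Enrichment of foreground windows over background windows is
a one-sided Fisher exact test on the 2x2 hit table.

The shipped REST/NRSE and E2F1 matrices are consensus-derived synthetic
stand-ins (built from the published consensus sequences, not from a
curated database) in JASPAR-style count-matrix text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import fisher_exact

from .core import GenomicInterval, Peak, ValidationError

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities.

    ``matrix`` is positions x 4 over A,C,G,T, normalised after adding
    ``pseudocount`` to each count; ``background`` is the null base
    distribution.  Scores are log2 odds in bits.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = None  # type: ignore[assignment]
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValidationError("PWM matrix must be positions x 4")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-9):
            raise ValidationError("background must sum to 1")
        rows = self.matrix.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValidationError("PWM rows must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray,
                    background: Optional[np.ndarray] = None,
                    pseudocount: float = 0.5) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        matrix = counts / counts.sum(axis=1, keepdims=True)
        return cls(name, matrix, background, pseudocount)

    @classmethod
    def from_consensus(cls, name: str, consensus: str,
                       strength: float = 0.97) -> "PWM":
        """Build a PWM from an IUPAC consensus (supports S,W,R,Y,K,M,N).

        ``strength`` is the total probability on the consensus base(s).
        """
        iupac = {"A": "A", "C": "C", "G": "G", "T": "T", "S": "CG",
                 "W": "AT", "R": "AG", "Y": "CT", "K": "GT", "M": "AC",
                 "N": "ACGT"}
        rows = []
        for ch in consensus.upper():
            allowed = iupac[ch]
            row = np.full(4, (1 - strength) / (4 - len(allowed))
                          if len(allowed) < 4 else 0.25)
            for b in allowed:
                row[BASES.index(b)] = strength / len(allowed)
            rows.append(row)
        return cls(name, np.array(rows))

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


def read_jaspar(path_or_text: str, pseudocount: float = 0.5) -> PWM:
    """Parse a JASPAR-style count matrix (A/C/G/T rows in brackets)."""
    if "\n" in path_or_text:
        text = path_or_text
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    name = "PWM"
    counts: Dict[str, List[float]] = {}
    for line in text.strip().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].strip().split()[0] or name
            continue
        base = line[0].upper()
        inner = line[line.find("[") + 1: line.find("]")] \
            if "[" in line else line[1:]
        counts[base] = [float(x) for x in inner.split()]
    if set(counts) != set(BASES):
        raise ValidationError("JASPAR matrix needs A, C, G and T rows")
    lengths = {len(v) for v in counts.values()}
    if len(lengths) != 1:
        raise ValidationError("unequal row lengths in count matrix")
    arr = np.array([counts[b] for b in BASES]).T  # positions x 4
    return PWM.from_counts(name, arr, pseudocount=pseudocount)


def load_builtin_pwm(name: str) -> PWM:
    """Load a shipped consensus-derived PWM ('rest_nrse' or 'e2f1')."""
    fname = {"rest_nrse": "rest_nrse_synthetic.jaspar",
             "e2f1": "e2f1_synthetic.jaspar"}[name]
    text = resources.files("chipexpr.data").joinpath(fname).read_text()
    return read_jaspar(text)


@dataclass
class MotifHit:
    window_id: str
    offset: int
    strand: str
    score: float


def summit_windows(
    peaks: Sequence[Peak], width: int,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> List[GenomicInterval]:
    """Fixed-width windows centred on peak summits.

    Each window is [summit − width/2, summit + width/2), truncated at
    chromosome bounds when lengths are known.
    """
    if width <= 0 or width % 2 != 0:
        raise ValidationError("width must be even and positive")
    half = width // 2
    windows = []
    for p in peaks:
        start = max(0, p.summit - half)
        end = p.summit + half
        if chrom_lengths is not None and p.chrom in chrom_lengths:
            end = min(end, chrom_lengths[p.chrom])
        windows.append(GenomicInterval(p.chrom, start, end, "."))
    return windows


def logodds_score(window_seq: str, pwm: PWM, offset: int, strand: str) -> float:
    """Log2-odds score of one placement; N contributes 0 at its position.

    The minus strand scores the reverse complement of the window slice.
    """
    L = len(pwm)
    if offset < 0 or offset + L > len(window_seq):
        raise ValidationError(
            f"offset {offset} + motif length {L} outside window of "
            f"{len(window_seq)} bp"
        )
    site = window_seq[offset: offset + L].upper()
    if strand == "-":
        site = reverse_complement(site)
    lo = pwm.log_odds
    score = 0.0
    for j, base in enumerate(site):
        if base == "N":
            continue
        try:
            score += lo[j, BASES.index(base)]
        except ValueError as exc:
            raise ValidationError(f"invalid base {base!r}") from exc
    return float(score)


def scan_windows(
    windows: Sequence[GenomicInterval],
    genome: Dict[str, str],
    pwm: PWM,
    score_threshold: float,
    window_ids: Optional[Sequence[str]] = None,
) -> Tuple[List[MotifHit], Dict[str, bool]]:
    """Scan every offset on both strands of each window.

    Returns all hits with score >= threshold plus a per-window has_hit
    flag.  Windows extending beyond the sequence end raise a bounds error.
    """
    ids = list(window_ids) if window_ids is not None else [
        f"{w.chrom}:{w.start}-{w.end}" for w in windows
    ]
    lo = pwm.log_odds
    L = len(pwm)
    hits: List[MotifHit] = []
    has_hit: Dict[str, bool] = {}
    for wid, w in zip(ids, windows):
        if w.chrom not in genome:
            raise ValidationError(f"window chromosome {w.chrom!r} not in genome")
        seq = genome[w.chrom]
        if w.end > len(seq):
            raise ValidationError(
                f"window {wid} extends beyond {w.chrom} length {len(seq)}"
            )
        sub = seq[w.start:w.end].upper()
        has_hit[wid] = False
        if len(sub) < L:
            continue
        idx = np.frombuffer(sub.encode(), dtype=np.uint8)
        code = np.full(idx.shape, -1, dtype=np.int8)
        for k, b in enumerate(BASES):
            code[idx == ord(b)] = k
        n_off = len(sub) - L + 1
        # vectorised log-odds over all offsets, N (code -1) scores 0
        fwd = np.zeros(n_off)
        rev = np.zeros(n_off)
        for j in range(L):
            c = code[j: j + n_off]
            valid = c >= 0
            fwd[valid] += lo[j, c[valid]]
            # minus strand: position j of the motif aligns to window base
            # offset+L-1-j, complemented
            c2 = code[L - 1 - j: L - 1 - j + n_off]
            valid2 = c2 >= 0
            rev[valid2] += lo[j, 3 - c2[valid2]]
        for strand, scores in (("+", fwd), ("-", rev)):
            for off in np.nonzero(scores >= score_threshold)[0]:
                hits.append(MotifHit(wid, int(off), strand,
                                     float(scores[off])))
                has_hit[wid] = True
    return hits, has_hit


def motif_enrichment_test(
    fg_windows: Sequence[GenomicInterval],
    bg_windows: Sequence[GenomicInterval],
    genome: Dict[str, str],
    pwm: PWM,
    threshold: Optional[float] = None,
) -> Dict[str, float]:
    """One-sided Fisher exact test for motif enrichment in foreground windows.

    Default threshold is 80% of the PWM's maximum log-odds score.  The
    odds ratio uses a Haldane 0.5 correction when any cell is zero.
    """
    if not fg_windows or not bg_windows:
        raise ValidationError("both window sets must be non-empty")
    if threshold is None:
        threshold = 0.8 * pwm.max_score
    _, fg_flags = scan_windows(fg_windows, genome, pwm, threshold,
                               [f"fg{i}" for i in range(len(fg_windows))])
    _, bg_flags = scan_windows(bg_windows, genome, pwm, threshold,
                               [f"bg{i}" for i in range(len(bg_windows))])
    fg_hit = sum(fg_flags.values())
    bg_hit = sum(bg_flags.values())
    fg_miss = len(fg_windows) - fg_hit
    bg_miss = len(bg_windows) - bg_hit
    table = [[fg_hit, fg_miss], [bg_hit, bg_miss]]
    _, p = fisher_exact(table, alternative="greater")
    cells = [fg_hit, fg_miss, bg_hit, bg_miss]
    if 0 in cells:
        a, b, c, d = (x + 0.5 for x in cells)
    else:
        a, b, c, d = cells
    return {
        "fg_hits": fg_hit, "fg_total": len(fg_windows),
        "bg_hits": bg_hit, "bg_total": len(bg_windows),
        "odds_ratio": (a * d) / (b * c),
        "p_value": float(p),
        "threshold_bits": float(threshold),
    }


def random_background_windows(
    chrom_lengths: Dict[str, int], width: int, n: int, seed: int
) -> List[GenomicInterval]:
    """Random same-width windows over the given chromosomes (the control set)."""
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)
    weights = np.array([chrom_lengths[c] - width for c in chroms], dtype=float)
    if np.any(weights <= 0):
        raise ValidationError("width exceeds a chromosome length")
    probs = weights / weights.sum()
    out = []
    for _ in range(n):
        c = chroms[rng.choice(len(chroms), p=probs)]
        start = int(rng.integers(0, chrom_lengths[c] - width))
        out.append(GenomicInterval(c, start, start + width, "."))
    return out


def write_hits_bed(hits: Sequence[MotifHit],
                   windows: Dict[str, GenomicInterval],
                   motif_length: int, path: str) -> None:
    """Hits as BED6 in genome coordinates, score = bits."""
    with open(path, "w") as fh:
        for h in hits:
            w = windows[h.window_id]
            start = w.start + h.offset
            fh.write(
                f"{w.chrom}\t{start}\t{start + motif_length}\t"
                f"{h.window_id}\t{h.score:.3f}\t{h.strand}\n"
            )
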