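"""Anchor-centred signal matrices and average profiles.

The heatmap substrate: a matrix of binned mean coverage around a list of
anchors (TSSs or peak summits), strand-aware so minus-strand anchors read
5'→3' in gene orientation, plus the per-bin average profile and the
expression sliding-window smoother used alongside signal-ordered heatmaps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import ConfigurationError, CoverageTrack, ValidationError


@dataclass
class ProfileMatrix:
    """anchors x bins matrix of mean per-base signal.

    ``bin_edges`` are offsets in bp relative to the anchor (length nbins+1);
    rows align with ``anchor_ids``.
    """

    anchor_ids: List[str]
    bin_edges: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bin_edges = np.asarray(self.bin_edges)
        if self.values.shape != (len(self.anchor_ids), len(self.bin_edges) - 1):
            raise ValidationError("ProfileMatrix shape mismatch")

    @property
    def nbins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_width(self) -> int:
        return int(self.bin_edges[1] - self.bin_edges[0])


def profile_matrix(
    track: CoverageTrack,
    anchors: Sequence[Tuple[str, int, str]],
    halfwindow: int,
    nbins: int,
    anchor_ids: Optional[Sequence[str]] = None,
    chrom_lengths: Optional[dict] = None,
) -> ProfileMatrix:
    """Binned mean coverage in [anchor-halfwindow, anchor+halfwindow).

    ``anchors`` are (chrom, position, strand) triples.  Bin value = mean
    per-base coverage over the bin's span; minus-strand anchors have their
    bins reversed so bin order is 5'→3' in gene orientation.  Portions of
    a window beyond the chromosome (position < 0, or >= chrom length when
    ``chrom_lengths`` is given) contribute only their covered bp to the
    bin mean; a bin with no covered bp is 0.
    """
    if nbins <= 0:
        raise ConfigurationError("nbins must be positive")
    if (2 * halfwindow) % nbins != 0:
        raise ConfigurationError(
            f"window of {2 * halfwindow} bp not divisible into {nbins} bins"
        )
    width = 2 * halfwindow // nbins
    edges = np.arange(-halfwindow, halfwindow + 1, width)
    values = np.zeros((len(anchors), nbins))
    for r, (chrom, pos, strand) in enumerate(anchors):
        limit = None if chrom_lengths is None else chrom_lengths.get(chrom)
        for b in range(nbins):
            lo = pos + int(edges[b])
            hi = pos + int(edges[b + 1])
            clo = max(lo, 0)
            chi = hi if limit is None else min(hi, limit)
            if chi <= clo:
                continue
            values[r, b] = track.integral(chrom, clo, chi) / (chi - clo)
        if strand == "-":
            values[r] = values[r, ::-1]
    ids = list(anchor_ids) if anchor_ids is not None else [
        f"{c}:{p}:{s}" for c, p, s in anchors
    ]
    return ProfileMatrix(ids, edges, values)


def average_profile(matrix: ProfileMatrix) -> np.ndarray:
    """Per-bin mean over anchors (the Fig-2A-style average profile)."""
    if matrix.values.shape[0] == 0:
        raise ValidationError("average_profile of an empty matrix")
    return matrix.values.mean(axis=0)


def order_anchors_by_signal(
    matrix: ProfileMatrix, center_halfwidth_bins: int
) -> List[str]:
    """Anchor ids sorted descending by mean central signal, ties by id.

    The heatmap y-axis ordering key: mean over the central
    2*center_halfwidth_bins bins.
    """
    if center_halfwidth_bins > matrix.nbins // 2:
        raise ConfigurationError("center_halfwidth_bins exceeds nbins/2")
    mid = matrix.nbins // 2
    lo, hi = mid - center_halfwidth_bins, mid + center_halfwidth_bins
    central = matrix.values[:, lo:hi].mean(axis=1)
    order = sorted(
        range(len(matrix.anchor_ids)),
        key=lambda i: (-central[i], matrix.anchor_ids[i]),
    )
    return [matrix.anchor_ids[i] for i in order]


def sliding_window_smooth(values: Sequence[float], window: int) -> np.ndarray:
    """Moving average, 'valid' mode: output[i] = mean(values[i:i+window]).

    Output length is len(values) - window + 1.  Used to smooth per-gene
    expression along a signal-ordered gene list.
    """
    arr = np.asarray(values, dtype=float)
    if window < 1:
        raise ValidationError("window must be >= 1")
    if window > arr.size:
        raise ValidationError(
            f"window {window} exceeds sequence length {arr.size}"
        )
    kernel = np.full(window, 1.0 / window)
    return np.convolve(arr, kernel, mode="valid")


def strided_window_smooth(values: Sequence[float], window: int,
                          step: int) -> np.ndarray:
    """Moving average evaluated every ``step`` positions (the stride variant)."""
    dense = sliding_window_smooth(values, window)
    return dense[::step]


def write_profile_matrix(matrix: ProfileMatrix, path: str,
                         sidecar_path: Optional[str] = None) -> None:
    """TSV of anchors x bins with a JSON sidecar of bin edges."""
    with open(path, "w") as fh:
        header = "\t".join(
            f"bin_{int(matrix.bin_edges[i])}_{int(matrix.bin_edges[i + 1])}"
            for i in range(matrix.nbins)
        )
        fh.write("anchor_id\t" + header + "\n")
        for aid, row in zip(matrix.anchor_ids, matrix.values):
            fh.write(aid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
    if sidecar_path:
        with open(sidecar_path, "w") as fh:
            json.dump({"bin_edges": [int(e) for e in matrix.bin_edges]}, fh)
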